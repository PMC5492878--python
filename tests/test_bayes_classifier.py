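"""Naive Bayes, Bayes-network structure search, posterior inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import imufall as f
from imufall.bayes_classifier import (
    DegenerateTrainingError,
    SchemaError,
    _discretize,
    log_posterior_matrix,
)
from imufall.windowing import FeatureMatrix, WindowInstance


def two_cluster_data(n=20):
    X = np.concatenate([np.zeros(n), np.full(n, 10.0)])[:, None]
    y = ["A"] * n + ["B"] * n
    return X, y


def test_gaussian_decision_boundary_at_midpoint():
    X, y = two_cluster_data(4)
    model = f.train_naive_bayes(X, y, feature_names=("v",))
    eps = 1e-3
    assert max(f.classify_instance(model, {"v": 5 - eps}).items(), key=lambda kv: kv[1])[0] == "A"
    assert max(f.classify_instance(model, {"v": 5 + eps}).items(), key=lambda kv: kv[1])[0] == "B"


def test_identical_feature_distributions_leave_the_prior():
    X = np.ones((9, 1))
    y = ["A"] * 6 + ["B"] * 3
    model = f.train_naive_bayes(X, y)
    post = f.classify_instance(model, [1.0])
    assert post["A"] == pytest.approx(2 / 3, abs=1e-9)
    assert post["B"] == pytest.approx(1 / 3, abs=1e-9)


def test_training_error_paths():
    with pytest.raises(DegenerateTrainingError):
        f.train_naive_bayes(np.zeros((4, 1)), ["A"] * 4)
    with pytest.raises(DegenerateTrainingError):
        f.train_naive_bayes(np.zeros((2, 1)), ["A", "B"])  # one instance per class
    with pytest.raises(ValueError):
        f.train_bayes_network(*two_cluster_data(), max_parents=-1)


def reference_discrete_nb(X, y, v, n_bins=10, alpha=0.5):
    """Independent discretised naive Bayes (explicit loops, linear space)."""
    classes = sorted(set(y))
    edges = [np.unique(np.quantile(X[:, i], np.linspace(0, 1, n_bins + 1)[1:-1]))
             for i in range(X.shape[1])]
    bins = _discretize(X, edges)
    vb = _discretize(np.asarray(v, float)[None, :], edges)[0]
    post = []
    for c in classes:
        mask = np.array([yi == c for yi in y])
        p = mask.mean()
        for i in range(X.shape[1]):
            B = len(edges[i]) + 1
            count = np.sum(bins[mask, i] == vb[i])
            p *= (count + alpha) / (mask.sum() + B * alpha)
        post.append(p)
    post = np.array(post)
    return dict(zip(classes, post / post.sum()))


def test_max_parents_zero_reduces_to_discretised_naive_bayes():
    rng = np.random.default_rng(4)
    X = np.concatenate([rng.normal(0, 1, (80, 3)), rng.normal(2, 1, (80, 3))])
    y = ["A"] * 80 + ["B"] * 80
    model = f.train_bayes_network(X, y, max_parents=0)
    assert all(p is None for p in model.parents)
    for row in X[::13]:
        ours = f.classify_instance(model, row)
        ref = reference_discrete_nb(X, y, row)
        for c in ours:
            assert ours[c] == pytest.approx(ref[c], abs=1e-10)


def test_duplicated_feature_is_linked_and_not_worse():
    rng = np.random.default_rng(11)
    base = np.concatenate([rng.normal(0, 1, 500), rng.normal(1.5, 1, 500)])
    X = np.column_stack([base, base])  # f2 duplicates f1
    y = ["A"] * 500 + ["B"] * 500
    model = f.train_bayes_network(X, y, feature_names=("f1", "f2"))
    assert model.parents.count(None) == 1  # one of the pair adopts the other
    # held-out accuracy of the network is not below naive Bayes on one split
    Xte = np.column_stack([base[::7], base[::7]])
    yte = np.array(y)[::7]
    nb = f.train_bayes_network(X, y, max_parents=0)

    def acc(m):
        lp = log_posterior_matrix(m, Xte)
        pred = [m.classes[i] for i in lp.argmax(axis=1)]
        return np.mean([p == t for p, t in zip(pred, yte)])
    assert acc(model) >= acc(nb)


def test_independent_features_learn_no_parents():
    rng = np.random.default_rng(21)
    n = 5000
    y = ["A"] * n + ["B"] * n
    X = np.column_stack([
        np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)]),
        np.concatenate([rng.normal(0, 1, n), rng.normal(-1, 1, n)]),
    ])
    model = f.train_bayes_network(X, y)
    assert all(p is None for p in model.parents)


def brute_force_posterior(model, v):
    """Enumerate the full joint of the class-rooted network and condition."""
    edges = model.bin_edges
    vb = _discretize(np.asarray(v, float)[None, :], edges)[0]
    states = [range(len(e) + 1) for e in edges]
    scores = []
    for ci in range(len(model.classes)):
        total = 0.0
        for assignment in itertools.product(*states):
            p = model.priors[ci]
            for i, b in enumerate(assignment):
                if model.parents[i] is None:
                    p *= model.cpts[i][ci, b]
                else:
                    p *= model.cpts[i][ci, assignment[model.parents[i]], b]
            if all(b == vb[i] for i, b in enumerate(assignment)):
                total += p
        scores.append(total)
    scores = np.array(scores)
    return dict(zip(model.classes, scores / scores.sum()))


def test_posterior_matches_joint_enumeration_oracle():
    # 2 features, 3 bins, 2 classes, correlated so a parent edge can appear
    rng = np.random.default_rng(33)
    base = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
    X = np.column_stack([base, base + rng.normal(0, 0.3, 400)])
    y = ["A"] * 200 + ["B"] * 200
    model = f.train_bayes_network(X, y, n_bins=3)
    for v in X[::37]:
        ours = f.classify_instance(model, v)
        ref = brute_force_posterior(model, v)
        for c in ours:
            assert ours[c] == pytest.approx(ref[c], abs=1e-10)


def test_out_of_range_values_fall_into_edge_bins():
    X, y = two_cluster_data(30)
    model = f.train_bayes_network(X, y)
    post = f.classify_instance(model, [1e9])
    assert all(np.isfinite(p) and p > 0 for p in post.values())
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)


@given(st.floats(-50, 50))
def test_posterior_normalised_and_finite(v):
    X, y = two_cluster_data(10)
    gm = f.train_naive_bayes(X, y)
    dm = f.train_bayes_network(X, y, n_bins=4)
    for model in (gm, dm):
        post = f.classify_instance(model, [v])
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(np.isfinite(p) for p in post.values())


def test_label_permutation_equivariance():
    rng = np.random.default_rng(5)
    X = np.concatenate([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
    y1 = ["A"] * 30 + ["B"] * 30
    y2 = ["B"] * 30 + ["A"] * 30  # renamed classes
    m1 = f.train_naive_bayes(X, y1)
    m2 = f.train_naive_bayes(X, y2)
    v = X[7]
    p1, p2 = f.classify_instance(m1, v), f.classify_instance(m2, v)
    assert p1["A"] == pytest.approx(p2["B"]) and p1["B"] == pytest.approx(p2["A"])


def test_schema_mismatch_rejected():
    X, y = two_cluster_data()
    model = f.train_naive_bayes(X, y, feature_names=("v",))
    with pytest.raises(SchemaError):
        f.classify_instance(model, {"other": 1.0})


def _window_model():
    rng = np.random.default_rng(9)
    X = np.concatenate([rng.normal(0, 1, (50, 1)), rng.normal(8, 1, (50, 1))])
    y = ["Wk"] * 50 + ["Bw-Fall"] * 50
    return f.train_naive_bayes(X, y, feature_names=("v",))


def test_unanimous_window_agrees_under_both_rules():
    model = _window_model()
    w = WindowInstance(0, FeatureMatrix(("v",), np.zeros((200, 1))))
    assert f.classify_window(model, w, rule="majority") == "Wk"
    assert f.classify_window(model, w, rule="mean_log_posterior") == "Wk"


def test_majority_rule_counts_votes():
    model = _window_model()
    values = np.concatenate([np.full(120, 8.0), np.zeros(80)])[:, None]
    w = WindowInstance(0, FeatureMatrix(("v",), values))
    assert f.classify_window(model, w, rule="majority") == "Bw-Fall"


def test_majority_tie_breaks_toward_the_fall_class():
    rng = np.random.default_rng(2)
    X = np.concatenate([rng.normal(0, 1, (50, 1)), rng.normal(8, 1, (50, 1))])
    y = ["Sd"] * 50 + ["Sd-Fall"] * 50
    model = f.train_naive_bayes(X, y, feature_names=("v",))
    values = np.concatenate([np.zeros(100), np.full(100, 8.0)])[:, None]
    w = WindowInstance(0, FeatureMatrix(("v",), values))
    assert f.classify_window(model, w, rule="majority") == "Sd-Fall"


def test_empty_window_rejected():
    model = _window_model()
    with pytest.raises(f.signal_features.EmptyInputError):
        f.classify_window(model, FeatureMatrix(("v",), np.zeros((0, 1))))


def test_more_features_do_not_reduce_training_fit(small_corpus):
    # echoes the feature-ablation ordering at the training-set level
    accel, gyro = f.default_kalman_params()
    windows9, windows3, labels = [], [], []
    for s in small_corpus[::4]:
        filt = f.filter_stream(s, accel, gyro)
        windows9.append(f.event_window(f.make_feature_vectors(filt, "FS9")))
        windows3.append(f.event_window(f.make_feature_vectors(filt, "FS3")))
        labels.append(s.label)

    def training_accuracy(windows):
        X = np.vstack([w.values for w in windows])
        y = np.concatenate([[l] * len(w) for w, l in zip(windows, labels)])
        model = f.train_bayes_network(X, y, feature_names=windows[0].names)
        pred = [f.classify_window(model, w) for w in windows]
        return np.mean([p == t for p, t in zip(pred, labels)])

    assert training_accuracy(windows9) >= training_accuracy(windows3)


def test_model_serialisation_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = np.concatenate([rng.normal(0, 1, (40, 2)), rng.normal(2, 1, (40, 2))])
    y = ["Wk"] * 40 + ["Sd"] * 40
    for model in (f.train_naive_bayes(X, y), f.train_bayes_network(X, y)):
        path = tmp_path / "model.json"
        f.save_model(model, path)
        back = f.load_model(path)
        v = X[3]
        assert f.classify_instance(back, v) == pytest.approx(f.classify_instance(model, v))
        assert back.graph == model.graph
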