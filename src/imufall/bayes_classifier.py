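"""Naive-Bayes and Bayes-network activity classifiers.

Both classifiers share one model container, :class:`BayesNetModel`, whose
graph always has the class node as a root parent of every feature node.  The
joint factorises as

    P(C, X_1..X_d) = P(C) * prod_i P(X_i | C, parents(X_i))

and the posterior over the six activity classes is the normalised product of
the class prior and the per-feature conditional factors, computed in log
space throughout (a 200-sample window multiplies 1800 factors under FS9, far
beyond float range in the linear domain).

* Naive Bayes: continuous features, one Gaussian per (class, feature).
* Bayes network: features discretised by equal-frequency binning (10 bins by
  default); conditional probability tables (CPTs) by maximum likelihood with
  Laplace smoothing (alpha = 0.5); structure learned by greedy hill-climbing
  over class-augmented networks scored by a decomposable Dirichlet marginal
  likelihood (K2-style), each feature node receiving at most ``max_parents``
  feature parents on top of the class node.

Window-level decisions aggregate per-sample posteriors either by majority
vote over argmax labels or by the window-averaged log posterior (default).
Ties break toward the fall classes: in a safety application a tie must
alarm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .signal_features import EmptyInputError, FALL_CLASSES
from .windowing import FeatureMatrix, WindowInstance

_LOG_2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-12

#: per-instance posterior: maps class label -> probability (sums to 1)
Posterior = dict


class DegenerateTrainingError(ValueError):
    """Training data lacks the class diversity needed to fit a classifier."""


class SchemaError(ValueError):
    """An instance's feature keys do not match the model's feature nodes."""


@dataclass
class BayesNetModel:
    """A class-rooted Bayes network over activity features.

    ``parents[i]`` is the index of feature i's feature parent (or None); the
    class node is implicitly a parent of every feature.  ``kind`` selects the
    likelihood: "gaussian" (continuous naive Bayes) or "discrete" (binned
    CPTs).
    """

    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    priors: np.ndarray
    kind: str
    # gaussian likelihood
    means: np.ndarray | None = None
    variances: np.ndarray | None = None
    # discrete likelihood
    bin_edges: list | None = None  # per feature: interior edges, strictly increasing
    parents: tuple | None = None
    cpts: list | None = None  # per feature: (C, B_i) or (C, B_parent, B_i)
    alpha: float = 0.5

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-9 or np.any(self.priors <= 0):
            raise ValueError("class priors must be strictly positive and sum to 1")
        if self.kind == "discrete":
            if self.parents is None:
                self.parents = tuple(None for _ in self.feature_names)
            for i, cpt in enumerate(self.cpts):
                if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                    raise ValueError(f"CPT rows for feature {self.feature_names[i]} must sum to 1")
        elif self.kind != "gaussian":
            raise ValueError(f"unknown likelihood kind {self.kind!r}")

    @property
    def graph(self) -> dict:
        """Parent map over nodes; the class node is named 'class'."""
        g = {"class": ()}
        for i, name in enumerate(self.feature_names):
            par = ["class"]
            if self.kind == "discrete" and self.parents[i] is not None:
                par.append(self.feature_names[self.parents[i]])
            g[name] = tuple(par)
        return g


# ---------------------------------------------------------------------------
# training helpers


def _as_matrix(instances, feature_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(instances, FeatureMatrix):
        return instances.values, instances.names
    if isinstance(instances, np.ndarray):
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(instances.shape[1]))
        return np.asarray(instances, dtype=float), tuple(feature_names)
    rows = list(instances)
    if not rows:
        raise EmptyInputError("no training instances")
    if isinstance(rows[0], Mapping):
        names = tuple(feature_names) if feature_names else tuple(rows[0].keys())
        X = np.array([[r[k] for k in names] for r in rows], dtype=float)
        return X, names
    X = np.asarray(rows, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    return X, tuple(feature_names)


def _class_index(y) -> tuple[np.ndarray, tuple[str, ...]]:
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise DegenerateTrainingError("training needs at least two classes")
    lookup = {c: i for i, c in enumerate(classes)}
    yi = np.array([lookup[v] for v in y.tolist()], dtype=int)
    counts = np.bincount(yi, minlength=len(classes))
    if counts.min() < 2:
        rare = classes[int(np.argmin(counts))]
        raise DegenerateTrainingError(f"class {rare!r} has fewer than 2 instances")
    return yi, classes


def train_naive_bayes(instances, y, feature_names=None) -> BayesNetModel:
    """Gaussian naive Bayes: class node is the sole parent of every feature."""
    X, names = _as_matrix(instances, feature_names)
    yi, classes = _class_index(y)
    C, d = len(classes), X.shape[1]
    priors = (np.bincount(yi, minlength=C) + 0.0) / len(yi)
    means = np.empty((C, d))
    variances = np.empty((C, d))
    pooled = X.var(axis=0)
    floor = np.maximum(1e-9 * np.where(pooled > 0, pooled, 1.0), _VAR_FLOOR)
    for c in range(C):
        Xc = X[yi == c]
        means[c] = Xc.mean(axis=0)
        variances[c] = np.maximum(Xc.var(axis=0), floor)
    return BayesNetModel(
        classes=classes, feature_names=names, priors=priors, kind="gaussian",
        means=means, variances=variances,
    )


def _equal_frequency_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(x, qs))
    return edges


def _discretize(X: np.ndarray, edges: list) -> np.ndarray:
    B = np.empty(X.shape, dtype=np.intp)
    for i, e in enumerate(edges):
        # values beyond the outermost edges land in the edge bins
        B[:, i] = np.searchsorted(e, X[:, i], side="right")
    return B


def _family_score(
    child_bins: np.ndarray, n_child: int, parent_cfg: np.ndarray, n_cfg: int, alpha: float
) -> float:
    """Dirichlet(alpha) log marginal likelihood of one feature node's CPT."""
    idx = parent_cfg * n_child + child_bins
    njk = np.bincount(idx, minlength=n_cfg * n_child).reshape(n_cfg, n_child)
    nj = njk.sum(axis=1)
    score = (
        gammaln(n_child * alpha) - gammaln(nj + n_child * alpha)
        + (gammaln(njk + alpha) - gammaln(alpha)).sum(axis=1)
    )
    return float(score.sum())


def _has_cycle(parents: list) -> bool:
    for start in range(len(parents)):
        seen = set()
        node = start
        while parents[node] is not None:
            node = parents[node]
            if node in seen or node == start:
                return True
            seen.add(node)
    return False


def train_bayes_network(
    instances,
    y,
    feature_names=None,
    max_parents: int = 1,
    n_bins: int = 10,
    alpha: float = 0.5,
    seed: int = 17,
) -> BayesNetModel:
    """Discretise, search the structure by greedy hill-climbing, fit CPTs.

    The class node is forced as a root parent of every feature; the search
    only adds feature-to-feature edges (at most ``max_parents`` per node)
    while the decomposable score improves.  The search itself is
    deterministic; ``seed`` is accepted for interface stability.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if max_parents > 1:
        raise ValueError("at most one feature parent per node is supported")
    X, names = _as_matrix(instances, feature_names)
    yi, classes = _class_index(y)
    C, d = len(classes), X.shape[1]
    priors = (np.bincount(yi, minlength=C) + 0.0) / len(yi)

    edges = [_equal_frequency_edges(X[:, i], n_bins) for i in range(d)]
    B = _discretize(X, edges)
    n_states = [len(e) + 1 for e in edges]

    parents: list = [None] * d
    if max_parents >= 1:
        base = [_family_score(B[:, i], n_states[i], yi, C, alpha) for i in range(d)]
        # candidate gains for adding j as parent of i (on top of the class node)
        while True:
            best_gain, best_edge = 0.0, None
            for i in range(d):
                if parents[i] is not None:
                    continue  # node already has its one feature parent
                for j in range(d):
                    if j == i:
                        continue
                    trial = parents.copy()
                    trial[i] = j
                    if _has_cycle(trial):
                        continue
                    cfg = yi * n_states[j] + B[:, j]
                    score = _family_score(B[:, i], n_states[i], cfg, C * n_states[j], alpha)
                    gain = score - base[i]
                    if gain > best_gain + 1e-9:
                        best_gain, best_edge = gain, (i, j)
            if best_edge is None:
                break
            i, j = best_edge
            parents[i] = j

    cpts = []
    for i in range(d):
        if parents[i] is None:
            counts = np.zeros((C, n_states[i]))
            np.add.at(counts, (yi, B[:, i]), 1.0)
        else:
            j = parents[i]
            counts = np.zeros((C, n_states[j], n_states[i]))
            np.add.at(counts, (yi, B[:, j], B[:, i]), 1.0)
        counts += alpha
        cpts.append(counts / counts.sum(axis=-1, keepdims=True))

    return BayesNetModel(
        classes=classes, feature_names=names, priors=priors, kind="discrete",
        bin_edges=edges, parents=tuple(parents), cpts=cpts, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# inference


def log_posterior_matrix(model: BayesNetModel, X: np.ndarray) -> np.ndarray:
    """Normalised (n, C) log posteriors for a feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {len(model.feature_names)}"
        )
    n, C = X.shape[0], len(model.classes)
    lp = np.tile(np.log(model.priors), (n, 1))
    if model.kind == "gaussian":
        for i in range(X.shape[1]):
            diff = X[:, i, None] - model.means[None, :, i]
            var = model.variances[None, :, i]
            lp += -0.5 * (diff * diff / var + np.log(var) + _LOG_2PI)
    else:
        Bm = _discretize(X, model.bin_edges)
        for i in range(X.shape[1]):
            logcpt = np.log(model.cpts[i])
            if model.parents[i] is None:
                lp += logcpt[:, Bm[:, i]].T
            else:
                j = model.parents[i]
                lp += logcpt[:, Bm[:, j], Bm[:, i]].T
    return lp - logsumexp(lp, axis=1, keepdims=True)


def _vector_to_row(model: BayesNetModel, v) -> np.ndarray:
    if isinstance(v, Mapping):
        missing = set(model.feature_names) - set(v.keys())
        extra = set(v.keys()) - set(model.feature_names)
        if missing or extra:
            raise SchemaError(
                f"feature keys mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        return np.array([[v[k] for k in model.feature_names]], dtype=float)
    arr = np.asarray(v, dtype=float).reshape(1, -1)
    return arr


def classify_instance(model: BayesNetModel, v) -> Posterior:
    """Posterior over classes for one feature vector (mapping or array)."""
    lp = log_posterior_matrix(model, _vector_to_row(model, v))[0]
    return dict(zip(model.classes, np.exp(lp)))


def _break_tie(labels: Sequence[str]) -> str:
    falls = sorted(l for l in labels if l in FALL_CLASSES)
    return falls[0] if falls else sorted(labels)[0]


def _argmax_labels(model: BayesNetModel, lp: np.ndarray) -> list:
    out = []
    for row in lp:
        best = np.flatnonzero(row == row.max())
        out.append(_break_tie([model.classes[i] for i in best]))
    return out


def classify_window(
    model: BayesNetModel, w, rule: str = "mean_log_posterior"
) -> str:
    """Window-level decision from per-sample posteriors.

    ``majority``: modal per-sample argmax label (ties toward the fall
    classes, then lexicographic).  ``mean_log_posterior`` (default): argmax
    of the window-averaged log posterior.
    """
    if isinstance(w, WindowInstance):
        elements = w.elements
    else:
        elements = w
    if isinstance(elements, FeatureMatrix):
        X = elements.values
    else:
        rows = list(elements)
        if not rows:
            raise EmptyInputError("cannot classify an empty window")
        X = np.vstack([_vector_to_row(model, r) for r in rows])
    if X.shape[0] == 0:
        raise EmptyInputError("cannot classify an empty window")
    lp = log_posterior_matrix(model, X)
    if rule == "mean_log_posterior":
        mean_lp = lp.mean(axis=0)
        best = np.flatnonzero(mean_lp == mean_lp.max())
        return _break_tie([model.classes[i] for i in best])
    if rule == "majority":
        labels = _argmax_labels(model, lp)
        counts: dict = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        top = max(counts.values())
        return _break_tie([l for l, c in counts.items() if c == top])
    raise ValueError(f"unknown window rule {rule!r}")


# ---------------------------------------------------------------------------
# model serialisation (structured text, versioned)


def save_model(model: BayesNetModel, path) -> None:
    doc = {
        "format": "imufall-bayes-model",
        "version": 1,
        "kind": model.kind,
        "classes": list(model.classes),
        "feature_names": list(model.feature_names),
        "priors": model.priors.tolist(),
        "alpha": model.alpha,
    }
    if model.kind == "gaussian":
        doc["means"] = model.means.tolist()
        doc["variances"] = model.variances.tolist()
    else:
        doc["bin_edges"] = [e.tolist() for e in model.bin_edges]
        doc["parents"] = [p for p in model.parents]
        doc["cpts"] = [c.tolist() for c in model.cpts]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> BayesNetModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "imufall-bayes-model":
        raise ValueError("not an imufall model file")
    common = dict(
        classes=tuple(doc["classes"]),
        feature_names=tuple(doc["feature_names"]),
        priors=np.array(doc["priors"]),
        kind=doc["kind"],
        alpha=doc["alpha"],
    )
    if doc["kind"] == "gaussian":
        return BayesNetModel(
            **common, means=np.array(doc["means"]), variances=np.array(doc["variances"])
        )
    return BayesNetModel(
        **common,
        bin_edges=[np.array(e) for e in doc["bin_edges"]],
        parents=tuple(doc["parents"]),
        cpts=[np.array(c) for c in doc["cpts"]],
    )
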