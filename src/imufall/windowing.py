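"""Per-sample feature vectors and sliding-window segmentation.

Each stream sample yields a feature vector drawn from one of three sets:

* ``FS9`` — a_x, a_y, a_z, a, w_x, w_y, w_z, w, theta (all nine)
* ``FS7`` — the raw axes plus trunk angle (no resultant magnitudes)
* ``FS3`` — the derived triple a, w, theta only

A fall lasts under 2 s, so the stream is segmented with a fixed-width
sliding window of 2 s (200 samples at 100 Hz).  Windows use 0-based,
half-open [start, start + width) indexing and are materialised as views of
the source feature matrix, never copies: mutating the source after
windowing is forbidden by contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_features import EmptyInputError, ImuStream, derived_feature_arrays

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS9": ("a_x", "a_y", "a_z", "a", "w_x", "w_y", "w_z", "w", "theta"),
    "FS7": ("a_x", "a_y", "a_z", "w_x", "w_y", "w_z", "theta"),
    "FS3": ("a", "w", "theta"),
}

DEFAULT_WIDTH = 200  # samples: 2 s at 100 Hz

FeatureVector = dict  # maps feature name -> value; keys = the active set


class FeatureMatrix(Sequence):
    """A (n, d) feature array posing as a sequence of FeatureVector dicts.

    Integer indexing builds the dict on demand; slicing returns a view-backed
    FeatureMatrix, which is how windows avoid copying.
    """

    def __init__(self, names: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(names):
            raise ValueError(f"values shape {values.shape} does not match {len(names)} names")
        self.names = tuple(names)
        self.values = values

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return FeatureMatrix(self.names, self.values[i])
        return dict(zip(self.names, (float(v) for v in self.values[i])))

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureMatrix({self.names}, n={len(self)})"


def make_feature_vectors(stream: ImuStream, feature_set: str = "FS9") -> FeatureMatrix:
    """One feature vector per sample of a (typically filtered) stream."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; expected one of {sorted(FEATURE_SETS)}")
    names = FEATURE_SETS[feature_set]
    a, theta, w = derived_feature_arrays(stream.acc, stream.gyro)
    columns = {
        "a_x": stream.acc[:, 0],
        "a_y": stream.acc[:, 1],
        "a_z": stream.acc[:, 2],
        "a": a,
        "w_x": stream.gyro[:, 0],
        "w_y": stream.gyro[:, 1],
        "w_z": stream.gyro[:, 2],
        "w": w,
        "theta": theta,
    }
    return FeatureMatrix(names, np.column_stack([columns[n] for n in names]))


@dataclass
class WindowInstance:
    """A contiguous fixed-width slice of the feature stream."""

    start_index: int
    elements: Sequence
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")
        if len(self.elements) == 0:
            raise EmptyInputError("a window must contain at least one element")

    def __len__(self) -> int:
        return len(self.elements)


def slide(
    vectors: Sequence,
    width: int = DEFAULT_WIDTH,
    step: int = 1,
    label: str | None = None,
) -> list[WindowInstance]:
    """All full-width windows at start indices 0, step, 2*step, ...

    Yields floor((n - width)/step) + 1 windows for n >= width, else none.
    Elements are views/slices of ``vectors`` (no copies).
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    n = len(vectors)
    out: list[WindowInstance] = []
    for start in range(0, n - width + 1, step):
        out.append(WindowInstance(start, vectors[start: start + width], label=label))
    return out


def slide_stream(
    stream: ImuStream,
    feature_set: str = "FS9",
    width: int = DEFAULT_WIDTH,
    step: int = 1,
) -> list[WindowInstance]:
    """Feature extraction + sliding in one call; windows inherit the stream label."""
    return slide(make_feature_vectors(stream, feature_set), width=width, step=step, label=stream.label)


def window_duration(fs: float, n_seconds: float) -> int:
    """Window length in samples for a given rate and duration (2 s at 100 Hz -> 200)."""
    if fs <= 0 or n_seconds <= 0:
        raise ValueError("fs and n_seconds must be positive")
    return int(round(fs * n_seconds))


def event_window(features: FeatureMatrix, width: int = DEFAULT_WIDTH) -> FeatureMatrix:
    """The single width-sample window centred on the peak resultant angular
    velocity (the event), clipped to the stream bounds.

    Training and evaluation use one window per recording; centring on the
    rotational peak captures the transition (fall impact, sit-down, bow)
    rather than the quiet lead-in.  Recordings shorter than ``width`` are
    returned whole.
    """
    n = len(features)
    if n <= width:
        return features
    if "w" in features.names:
        w = features.values[:, features.names.index("w")]
    else:
        wi = [features.names.index(k) for k in ("w_x", "w_y", "w_z")]
        w = np.linalg.norm(features.values[:, wi], axis=1)
    centre = int(np.argmax(w))
    start = min(max(centre - width // 2, 0), n - width)
    return features[start: start + width]
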