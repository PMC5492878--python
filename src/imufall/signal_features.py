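"""Raw IMU stream containers and the trunk-activity feature model.

A body-worn sensor on the upper trunk reports tri-axial acceleration (units
of g) and tri-axial angular velocity (deg/s) at a fixed rate (100 Hz by
default).  The axis convention follows the trunk frame: X is the trunk's
longitudinal axis, so standing aligns X with gravity and the static
accelerometer reads approximately (1, 0, 0) g.

Three derived quantities summarise posture and motion at each instant:

* resultant acceleration  a(t)  = ||(a_x, a_y, a_z)||        [g]
* trunk angle             theta(t) = arccos(a_x / a(t))      [degrees]
* resultant angular rate  w(t)  = ||(w_x, w_y, w_z)||        [deg/s]

The trunk angle is ~0 deg standing and ~90 deg lying; a fall drives it from
the former to the latter within a couple of seconds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: canonical activity labels: four activities of daily living and two falls
ACTIVITY_CLASSES: tuple[str, ...] = ("Wk", "Sd", "Sq", "Bw", "Sd-Fall", "Bw-Fall")
FALL_CLASSES: tuple[str, ...] = ("Sd-Fall", "Bw-Fall")
ADL_CLASSES: tuple[str, ...] = ("Wk", "Sd", "Sq", "Bw")
#: optional extra classes (excluded from the six-class experiment)
STAIR_CLASSES: tuple[str, ...] = ("StairUp", "StairDown")

DEFAULT_FS = 100.0  # Hz

_CSV_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


class InvalidSampleError(ValueError):
    """A channel value is non-finite or otherwise unusable."""


class DegenerateOrientationError(ValueError):
    """Trunk angle requested for a zero-magnitude acceleration vector."""


class EmptyInputError(ValueError):
    """An operation that needs at least one sample received none."""


class ImuSample(NamedTuple):
    """One reading: time in s, acceleration in g, angular velocity in deg/s."""

    t: float
    a_x: float
    a_y: float
    a_z: float
    w_x: float
    w_y: float
    w_z: float


class DerivedFeatures(NamedTuple):
    """Per-sample derived features: resultant accel (g), trunk angle (deg),
    resultant angular velocity (deg/s)."""

    a: float
    theta: float
    w: float


@dataclass
class ImuStream:
    """A fixed-rate IMU recording.

    Channels are stored as numpy arrays: ``t`` of shape (n,), ``acc`` and
    ``gyro`` of shape (n, 3).  ``label``, when present, must be one of
    :data:`ACTIVITY_CLASSES`.  Indexing returns :class:`ImuSample` records.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float = DEFAULT_FS
    label: str | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"channel shapes {self.acc.shape}/{self.gyro.shape} do not match "
                f"{n} timestamps"
            )
        if n == 0:
            raise EmptyInputError("an ImuStream must contain at least one sample")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            bad = int(
                np.flatnonzero(
                    ~(np.isfinite(self.acc).all(axis=1) & np.isfinite(self.gyro).all(axis=1))
                )[0]
            )
            raise InvalidSampleError(f"non-finite channel value at sample {bad}")
        if self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs, atol=1e-6):
                raise ValueError(f"timestamps are not spaced at 1/fs = {1.0 / self.fs} s")
        if self.label is not None and self.label not in ACTIVITY_CLASSES + STAIR_CLASSES:
            raise ValueError(
                f"unknown activity label {self.label!r}; expected one of {ACTIVITY_CLASSES + STAIR_CLASSES}"
            )

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(
            float(self.t[i]),
            float(self.acc[i, 0]),
            float(self.acc[i, 1]),
            float(self.acc[i, 2]),
            float(self.gyro[i, 0]),
            float(self.gyro[i, 1]),
            float(self.gyro[i, 2]),
        )

    def __iter__(self) -> Iterator[ImuSample]:
        return (self[i] for i in range(len(self)))

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[ImuSample],
        fs: float = DEFAULT_FS,
        label: str | None = None,
        subject: int | None = None,
    ) -> "ImuStream":
        rows = list(samples)
        if not rows:
            raise EmptyInputError("cannot build a stream from zero samples")
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1:4], arr[:, 4:7], fs=fs, label=label, subject=subject)

    def replace_channels(self, acc: np.ndarray, gyro: np.ndarray) -> "ImuStream":
        """New stream with identical timestamps/metadata but new channel data."""
        return ImuStream(self.t.copy(), acc, gyro, fs=self.fs, label=self.label, subject=self.subject)


# ---------------------------------------------------------------------------
# derived features


def _check_finite(name: str, *values: float) -> None:
    for axis, v in zip("xyz", values):
        if not np.isfinite(v):
            raise InvalidSampleError(f"non-finite {name} value on {axis} axis: {v!r}")


def resultant_acceleration(a_x: float, a_y: float, a_z: float) -> float:
    """Euclidean norm of the tri-axial acceleration vector, in g."""
    _check_finite("acceleration", a_x, a_y, a_z)
    return float(np.sqrt(a_x * a_x + a_y * a_y + a_z * a_z))


def trunk_angle(a_x: float, a_y: float, a_z: float) -> float:
    """Angle between the trunk X axis and the measured acceleration, in degrees.

    With gravity dominating the accelerometer reading this is the trunk
    inclination: ~0 deg standing, ~90 deg lying.  Undefined for a
    zero-magnitude vector (a resting IMU reads ~1 g, so zero magnitude
    signals corrupt data and raises :class:`DegenerateOrientationError`).
    """
    _check_finite("acceleration", a_x, a_y, a_z)
    norm = np.sqrt(a_x * a_x + a_y * a_y + a_z * a_z)
    if norm == 0.0:
        raise DegenerateOrientationError(
            "trunk angle undefined for zero-magnitude acceleration vector"
        )
    return float(np.degrees(np.arccos(np.clip(a_x / norm, -1.0, 1.0))))


def resultant_angular_velocity(w_x: float, w_y: float, w_z: float) -> float:
    """Euclidean norm of the tri-axial angular velocity, in deg/s."""
    _check_finite("angular velocity", w_x, w_y, w_z)
    return float(np.sqrt(w_x * w_x + w_y * w_y + w_z * w_z))


def derived_feature_arrays(acc: np.ndarray, gyro: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (a, theta, w) for (n, 3) channel arrays."""
    a = np.linalg.norm(acc, axis=1)
    if np.any(a == 0.0):
        bad = int(np.flatnonzero(a == 0.0)[0])
        raise DegenerateOrientationError(
            f"zero-magnitude acceleration vector at sample {bad}"
        )
    theta = np.degrees(np.arccos(np.clip(acc[:, 0] / a, -1.0, 1.0)))
    w = np.linalg.norm(gyro, axis=1)
    return a, theta, w


def derive_features(stream: ImuStream) -> list[DerivedFeatures]:
    """One :class:`DerivedFeatures` record per sample, in stream order."""
    if len(stream) == 0:  # pragma: no cover - ImuStream forbids emptiness
        raise EmptyInputError("cannot derive features from an empty stream")
    a, theta, w = derived_feature_arrays(stream.acc, stream.gyro)
    return [DerivedFeatures(float(ai), float(ti), float(wi)) for ai, ti, wi in zip(a, theta, w)]


# ---------------------------------------------------------------------------
# stream CSV format
#
# header line `t,ax,ay,az,gx,gy,gz`; one row per sample; optional comment
# lines `# label=<class>` and `# fs=<Hz>` before the header.  Values are
# written with 9 significant-plus decimals, so round-trips agree to 1e-9.


def write_stream_csv(stream: ImuStream, path_or_buf) -> None:
    """Write a stream in the documented CSV format (comments + header)."""
    header = []
    if stream.fs != DEFAULT_FS:
        header.append(f"# fs={stream.fs:g}\n")
    if stream.label is not None:
        header.append(f"# label={stream.label}\n")
    if stream.subject is not None:
        header.append(f"# subject={stream.subject}\n")
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.acc, stream.gyro]), columns=list(_CSV_COLUMNS)
    )
    body = df.to_csv(index=False, float_format="%.9f")
    text = "".join(header) + body
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_stream_csv(path_or_buf) -> ImuStream:
    """Read a stream CSV; tolerates both comment-annotated and bare files."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    fs = DEFAULT_FS
    label = None
    subject = None
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line.lstrip("# ").partition("=")
        key, value = key.strip(), value.strip()
        if key == "fs":
            fs = float(value)
        elif key == "label":
            label = value
        elif key == "subject":
            subject = int(value)
    df = pd.read_csv(io.StringIO(text), comment="#")
    if list(df.columns) != list(_CSV_COLUMNS):
        raise ValueError(
            f"unexpected stream CSV columns {list(df.columns)}; expected {list(_CSV_COLUMNS)}"
        )
    arr = df.to_numpy(dtype=float)
    return ImuStream(arr[:, 0], arr[:, 1:4], arr[:, 4:7], fs=fs, label=label, subject=subject)
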