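"""Autoregressive identification of static sensor noise and Kalman parameters.

A static calibration recording (sensor at rest, ~2 min at 100 Hz) is used to
fit AR(p) models, p in {1, 2, 3}, per axis.  Akaike's final prediction error

    FPE = sigma_hat^2 * (n + p + 1) / (n - p - 1)

selects the model order: the lowest order whose FPE is within a configurable
relative factor of the best candidate wins, so AR(1) is chosen whenever the
higher orders improve FPE only marginally.  The per-axis AR(1) coefficient
then supplies the diagonal of the Kalman state-transition matrix A, the FPE
supplies the process-noise diagonal Q, and the measurement-noise diagonal R
is a configured constant.

Accelerometer axes carry a gravity offset, so series are mean-removed before
fitting (an AR model of a non-centred near-unit-root series is ill-posed);
the mean is carried into :class:`KalmanParams` as a state offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .signal_features import EmptyInputError, ImuStream

#: measurement-noise diagonals as configured in the reference system
DEFAULT_R_ACCEL = (2e-5, 2e-5, 3e-5)  # g^2
DEFAULT_R_GYRO = (0.002, 0.00087, 0.00109)  # (deg/s)^2


class DegenerateFitError(ValueError):
    """AR fit requested on a constant series."""


class InsufficientDataError(ValueError):
    """Series too short for the requested AR order."""


@dataclass(frozen=True)
class ArFit:
    """AR(p) fit of one axis: coefficients a_1..a_p, residual variance, FPE."""

    order: int
    coefficients: tuple[float, ...]
    residual_variance: float
    fpe: float
    n_samples: int
    mean: float = 0.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order:
            raise ValueError("coefficient count must equal the AR order")


@dataclass(frozen=True)
class KalmanParams:
    """Diagonal Kalman parameterisation of one tri-axial channel.

    A, Q, R are 3x3 diagonal; H is the identity (states observed directly);
    the control input B*U is fixed to zero.  ``mean`` is the per-axis offset
    removed before AR fitting; the filter subtracts it from measurements and
    adds it back on output.
    """

    A: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    H: np.ndarray = field(default_factory=lambda: np.eye(3))
    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("A", "Q", "R", "H"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3, got {m.shape}")
            object.__setattr__(self, name, m)
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        if np.any(np.diag(self.Q) <= 0) or np.any(np.diag(self.R) <= 0):
            raise ValueError("Q and R diagonals must be strictly positive")


def fpe_from_residual(residual_variance: float, n: int, p: int) -> float:
    """Akaike's final prediction error."""
    return residual_variance * (n + p + 1) / (n - p - 1)


def fit_ar(series: Sequence[float], order: int, method: str = "ols") -> ArFit:
    """Fit an AR(order) model to a scalar series.

    ``method='ols'`` regresses x_t on its p lags (conditional maximum
    likelihood, no intercept) after mean removal; ``method='yule_walker'``
    uses the Yule-Walker moment equations instead (differences are O(1/n)).
    """
    if order not in (1, 2, 3):
        raise ValueError(f"AR order must be 1, 2 or 3, got {order}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n < 10 * order:
        raise InsufficientDataError(
            f"need at least {10 * order} samples for AR({order}), got {n}"
        )
    mean = float(x.mean())
    xc = x - mean
    if np.allclose(xc, 0.0):
        raise DegenerateFitError("cannot fit an AR model to a constant series")
    if method == "ols":
        # design matrix of lagged values: predict x_t from x_{t-1}..x_{t-p}
        y = xc[order:]
        X = np.column_stack([xc[order - k: n - k] for k in range(1, order + 1)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = float(np.mean(resid**2))
    elif method == "yule_walker":
        coef, sigma = yule_walker(xc, order=order, method="mle")
        y = xc[order:]
        X = np.column_stack([xc[order - k: n - k] for k in range(1, order + 1)])
        resid = y - X @ coef
        sigma2 = float(np.mean(resid**2))
    else:
        raise ValueError(f"unknown AR estimation method {method!r}")
    return ArFit(
        order=order,
        coefficients=tuple(float(c) for c in coef),
        residual_variance=sigma2,
        fpe=fpe_from_residual(sigma2, n, order),
        n_samples=n,
        mean=mean,
    )


def select_order(fits: Sequence[ArFit], rel_factor: float = 2.0) -> ArFit:
    """Pick the lowest-order fit whose FPE is within ``rel_factor`` of the best.

    Higher orders routinely shave a little off the FPE; when the improvement
    is within the same decade the simplest model is preferred, so a static
    IMU calibration selects AR(1).
    """
    if not fits:
        raise EmptyInputError("select_order needs at least one candidate fit")
    best = min(f.fpe for f in fits)
    for f in sorted(fits, key=lambda f: f.order):
        if f.fpe <= rel_factor * best:
            return f
    return min(fits, key=lambda f: f.fpe)  # pragma: no cover - loop always returns


def build_kalman_params(
    fit_x: ArFit,
    fit_y: ArFit,
    fit_z: ArFit,
    r_diagonal: Sequence[float],
) -> KalmanParams:
    """Assemble diagonal Kalman parameters from three per-axis AR(1) fits.

    A = diag(a_1 per axis); Q = diag(FPE per axis); R = diag(r_diagonal);
    H = I.  The fits' means become the state offset.
    """
    fits = (fit_x, fit_y, fit_z)
    for axis, f in zip("xyz", fits):
        if f.order != 1:
            raise ValueError(f"{axis}-axis fit has order {f.order}; expected AR(1)")
    r = np.asarray(r_diagonal, dtype=float)
    if r.shape != (3,) or np.any(r <= 0):
        raise ValueError("r_diagonal must be three strictly positive values")
    return KalmanParams(
        A=np.diag([f.coefficients[0] for f in fits]),
        Q=np.diag([f.fpe for f in fits]),
        R=np.diag(r),
        mean=np.array([f.mean for f in fits]),
    )


def calibrate_channels(
    calibration: ImuStream,
    r_accel: Sequence[float] = DEFAULT_R_ACCEL,
    r_gyro: Sequence[float] = DEFAULT_R_GYRO,
    orders: Sequence[int] = (1, 2, 3),
    method: str = "ols",
) -> tuple[KalmanParams, KalmanParams]:
    """Full calibration: per-axis AR order selection on a static recording,
    returning (accelerometer params, gyroscope params)."""
    chosen: dict[str, list[ArFit]] = {"acc": [], "gyro": []}
    for name, channel in (("acc", calibration.acc), ("gyro", calibration.gyro)):
        for axis in range(3):
            fits = [fit_ar(channel[:, axis], p, method=method) for p in orders]
            sel = select_order(fits)
            if sel.order != 1:
                # Q/A derivation needs AR(1); fall back to the order-1 fit
                sel = next(f for f in fits if f.order == 1)
            chosen[name].append(sel)
    return (
        build_kalman_params(*chosen["acc"], r_diagonal=r_accel),
        build_kalman_params(*chosen["gyro"], r_diagonal=r_gyro),
    )


def default_kalman_params() -> tuple[KalmanParams, KalmanParams]:
    """The reference-system parameter sets for a standing trunk sensor.

    Accelerometer: A = diag(0.9974, 1, 0.9953), Q = diag(4.3e-5, 3.29e-5,
    5.38e-5) g^2, R = diag(2e-5, 2e-5, 3e-5) g^2, gravity offset (1, 0, 0) g.
    Gyroscope: A = diag(1, 0.9269, 0.9997), Q = diag(1.2e-3, 1.0e-3, 1.1e-3)
    (deg/s)^2, R = diag(2e-3, 8.7e-4, 1.09e-3) (deg/s)^2, zero offset.
    """
    accel = KalmanParams(
        A=np.diag([0.9974, 1.0, 0.9953]),
        Q=np.diag([4.3e-5, 3.29e-5, 5.38e-5]),
        R=np.diag(DEFAULT_R_ACCEL),
        mean=np.array([1.0, 0.0, 0.0]),
    )
    gyro = KalmanParams(
        A=np.diag([1.0, 0.9269, 0.9997]),
        Q=np.diag([0.0012, 0.0010, 0.0011]),
        R=np.diag(DEFAULT_R_GYRO),
    )
    return accel, gyro


# ---------------------------------------------------------------------------
# calibration file format (structured text consumed by the filter stage)


def write_calibration(accel: KalmanParams, gyro: KalmanParams, path) -> None:
    lines = ["# imufall calibration v1"]
    for name, p in (("accel", accel), ("gyro", gyro)):
        for key, vec in (
            ("a1", np.diag(p.A)),
            ("q", np.diag(p.Q)),
            ("r", np.diag(p.R)),
            ("mean", p.mean),
        ):
            vals = ",".join(repr(float(v)) for v in vec)
            lines.append(f"{name}.{key}={vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calibration(path) -> tuple[KalmanParams, KalmanParams]:
    values: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, payload = line.partition("=")
            values[key] = np.array([float(v) for v in payload.split(",")])
    params = []
    for name in ("accel", "gyro"):
        params.append(
            KalmanParams(
                A=np.diag(values[f"{name}.a1"]),
                Q=np.diag(values[f"{name}.q"]),
                R=np.diag(values[f"{name}.r"]),
                mean=values[f"{name}.mean"],
            )
        )
    return params[0], params[1]
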