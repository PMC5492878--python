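"""Discrete Kalman filter for tri-axial IMU channels.

The filter runs the textbook predict/update recursion with the AR-derived
parameters of :mod:`imufall.ar_model`:

    predict:  x(k|k-1) = A x(k-1|k-1)            (B*U = 0)
              P(k|k-1) = A P(k-1|k-1) A' + Q
    update:   Kg(k)    = P(k|k-1) H' (H P(k|k-1) H' + R)^-1
              x(k|k)   = x(k|k-1) + Kg(k) (z(k) - H x(k|k-1))
              P(k|k)   = (I - Kg(k) H) P(k|k-1)

Acceleration and angular velocity run as two independent 3-state filters;
because A, Q, R, H are all diagonal this is equivalent to six independent
scalar filters, which is what :func:`filter_stream` executes for speed.
Initialisation: x_0 = first measurement, P_0 = R (avoids a start-up
transient).  When the AR model was identified on mean-removed data the
filter runs on mean-removed measurements and restores the offset on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ar_model import KalmanParams
from .signal_features import ImuStream


@dataclass
class KalmanState:
    """State estimate x(k|k) and its error covariance P(k|k)."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.x.shape != (3,) or self.P.shape != (3, 3):
            raise ValueError(f"state must be (3,)/(3,3), got {self.x.shape}/{self.P.shape}")
        if not np.allclose(self.P, self.P.T, atol=1e-9):
            raise ValueError("P must be symmetric")
        if np.linalg.eigvalsh(self.P).min() < -1e-10:
            raise ValueError("P must be positive semidefinite")


def predict(state: KalmanState, params: KalmanParams) -> tuple[np.ndarray, np.ndarray]:
    """Time update: returns (x(k|k-1), P(k|k-1)); the control term is zero."""
    A, Q = params.A, params.Q
    x_pred = A @ state.x
    P_pred = A @ state.P @ A.T + Q
    P_pred = 0.5 * (P_pred + P_pred.T)
    return x_pred, P_pred


def update(
    x_pred: np.ndarray,
    P_pred: np.ndarray,
    z: np.ndarray,
    params: KalmanParams,
) -> KalmanState:
    """Measurement update with gain Kg = P H'(H P H' + R)^-1."""
    x_pred = np.asarray(x_pred, dtype=float)
    P_pred = np.asarray(P_pred, dtype=float)
    z = np.asarray(z, dtype=float)
    if x_pred.shape != (3,) or P_pred.shape != (3, 3) or z.shape != (3,):
        raise ValueError("predicted state, covariance and measurement must be (3,), (3,3), (3,)")
    H, R = params.H, params.R
    S = H @ P_pred @ H.T + R
    Kg = P_pred @ H.T @ np.linalg.inv(S)
    x = x_pred + Kg @ (z - H @ x_pred)
    P = (np.eye(3) - Kg @ H) @ P_pred
    P = 0.5 * (P + P.T)
    return KalmanState(x=x, P=P)


def _filter_axis(z: np.ndarray, a: float, q: float, r: float) -> np.ndarray:
    """Scalar Kalman recursion along one axis (plain-float loop for speed)."""
    out = np.empty_like(z)
    x = float(z[0])
    p = r
    out[0] = x
    for k in range(1, z.shape[0]):
        xp = a * x
        pp = a * a * p + q
        kg = pp / (pp + r)
        x = xp + kg * (float(z[k]) - xp)
        p = (1.0 - kg) * pp
        out[k] = x
    return out


def filter_channel(z: np.ndarray, params: KalmanParams) -> np.ndarray:
    """Filter one (n, 3) channel; diagonal parameters make the 3-state filter
    exactly three scalar filters."""
    z = np.asarray(z, dtype=float)
    zc = z - params.mean
    a, q, r = np.diag(params.A), np.diag(params.Q), np.diag(params.R)
    out = np.empty_like(zc)
    for axis in range(3):
        out[:, axis] = _filter_axis(zc[:, axis], float(a[axis]), float(q[axis]), float(r[axis]))
    return out + params.mean


def filter_stream(
    stream: ImuStream,
    accel_params: KalmanParams,
    gyro_params: KalmanParams,
) -> ImuStream:
    """Return a stream of identical length/timestamps with both tri-axial
    channels replaced by their filtered estimates."""
    acc = filter_channel(stream.acc, accel_params)
    gyro = filter_channel(stream.gyro, gyro_params)
    return stream.replace_channels(acc, gyro)
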