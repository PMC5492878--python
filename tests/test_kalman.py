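"""Predict/update algebra, limiting cases, Riccati convergence, denoising."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

import imufall as f
from imufall.kalman import KalmanState, filter_channel
from conftest import constant_stream


def params(a, q, r, mean=(0, 0, 0)):
    return f.KalmanParams(A=np.diag(a), Q=np.diag(q), R=np.diag(r), mean=np.array(mean))


IDENTITY = params((1, 1, 1), (1e-300, 1e-300, 1e-300), (1, 1, 1))


def test_predict_identity_dynamics():
    state = KalmanState(x=np.array([1.0, 2, 3]), P=np.eye(3))
    x_pred, P_pred = f.predict(state, IDENTITY)
    np.testing.assert_allclose(x_pred, [1, 2, 3])
    np.testing.assert_allclose(P_pred, np.eye(3), atol=1e-250)


def test_predict_halving_dynamics():
    p = params((0.5, 0.5, 0.5), (1, 1, 1), (1, 1, 1))
    state = KalmanState(x=np.full(3, 2.0), P=np.eye(3))
    x_pred, P_pred = f.predict(state, p)
    np.testing.assert_allclose(x_pred, [1, 1, 1])
    np.testing.assert_allclose(P_pred, np.diag([1.25, 1.25, 1.25]))


def test_predict_from_zero_covariance_returns_q():
    accel, _ = f.default_kalman_params()
    state = KalmanState(x=np.zeros(3), P=np.zeros((3, 3)))
    x_pred, P_pred = f.predict(state, accel)
    np.testing.assert_allclose(x_pred, 0)
    np.testing.assert_allclose(P_pred, accel.Q)


def test_update_scalar_closed_form():
    # p = 1, r = 1, x_pred = 0, z = 1  ->  kg = 0.5, x = 0.5, p_post = 0.5
    state = f.update(np.zeros(3), np.eye(3), np.ones(3), IDENTITY)
    np.testing.assert_allclose(state.x, 0.5, atol=1e-12)
    np.testing.assert_allclose(state.P, 0.5 * np.eye(3), atol=1e-12)


def test_update_limiting_cases():
    trusting = params((1, 1, 1), (1, 1, 1), (1e-12, 1e-12, 1e-12))
    state = f.update(np.zeros(3), np.eye(3), np.array([1.0, -2, 3]), trusting)
    np.testing.assert_allclose(state.x, [1, -2, 3], atol=1e-9)

    state = f.update(np.array([4.0, 5, 6]), np.zeros((3, 3)), np.zeros(3), IDENTITY)
    np.testing.assert_allclose(state.x, [4, 5, 6])  # Kg = 0: measurement ignored


def test_update_shape_errors():
    with pytest.raises(ValueError):
        f.update(np.zeros(2), np.eye(3), np.zeros(3), IDENTITY)


def test_gain_diagonal_in_unit_interval():
    accel, gyro = f.default_kalman_params()
    for p in (accel, gyro):
        P_pred = p.Q * 5
        S = p.H @ P_pred @ p.H.T + p.R
        Kg = P_pred @ p.H.T @ np.linalg.inv(S)
        d = np.diag(Kg)
        assert np.all(d >= 0) and np.all(d < 1)


def test_constant_stream_is_a_fixed_point():
    # A = I: zero innovation at every step once x_0 = z_0
    s = constant_stream(acc=(0.3, -0.2, 0.9), gyro=(5, 0, -3), n=40)
    out = f.filter_stream(s, IDENTITY, IDENTITY)
    np.testing.assert_allclose(out.acc, s.acc, atol=1e-12)
    np.testing.assert_allclose(out.gyro, s.gyro, atol=1e-12)
    # default params: a stream resting at the state offset is also invariant
    accel, gyro = f.default_kalman_params()
    s = constant_stream(acc=(1.0, 0.0, 0.0), gyro=(0, 0, 0), n=40)
    out = f.filter_stream(s, accel, gyro)
    np.testing.assert_allclose(out.acc, s.acc, atol=1e-12)
    np.testing.assert_allclose(out.t, s.t)


def test_filter_reduces_variance_on_static_stream(noise):
    stream = f.generate_static_calibration(noise, duration_s=20)
    accel, gyro = f.default_kalman_params()
    out = f.filter_stream(stream, accel, gyro)
    truth_acc = np.array([1.0, 0, 0])
    for axis in range(3):
        raw = np.mean((stream.acc[:, axis] - truth_acc[axis]) ** 2)
        filt = np.mean((out.acc[:, axis] - truth_acc[axis]) ** 2)
        assert filt < raw
        assert np.mean(out.gyro[:, axis] ** 2) < np.mean(stream.gyro[:, axis] ** 2)


def scalar_kalman(z, a, q, r):
    """Independent scalar recursion used as the oracle."""
    x, p = z[0], r
    out = [x]
    for zk in z[1:]:
        xp, pp = a * x, a * a * p + q
        kg = pp / (pp + r)
        x = xp + kg * (zk - xp)
        p = (1 - kg) * pp
        out.append(x)
    return np.array(out)


def test_step_response_matches_scalar_recursion_oracle():
    z = np.zeros(300)
    z[100:] = 1.0
    oracle = scalar_kalman(z, a=1.0, q=1e-4, r=1e-2)
    lag = int(np.argmax(oracle[100:] >= 0.9))
    assert 0 < lag < 100  # estimate crosses 0.9 within a finite lag
    p = params((1, 1, 1), (1e-4,) * 3, (1e-2,) * 3)
    out = filter_channel(np.column_stack([z, z, z]), p)
    np.testing.assert_allclose(out[:, 0], oracle, atol=1e-12)
    assert int(np.argmax(out[100:, 0] >= 0.9)) == lag


def test_matrix_and_scalar_filters_agree():
    # diagonal A/Q/R/H: the 3-state filter is three independent scalar filters
    rng = np.random.default_rng(0)
    z = rng.normal(0, 1, (200, 3)) + [1.0, 0, 0]
    accel, _ = f.default_kalman_params()
    fast = filter_channel(z, accel)
    state = KalmanState(x=z[0] - accel.mean, P=accel.R.copy())
    ref = [state.x + accel.mean]
    for k in range(1, z.shape[0]):
        x_pred, P_pred = f.predict(state, accel)
        state = f.update(x_pred, P_pred, z[k] - accel.mean, accel)
        ref.append(state.x + accel.mean)
        assert np.allclose(state.P, state.P.T, atol=1e-12)
    np.testing.assert_allclose(fast, np.array(ref), rtol=0, atol=1e-12)


@pytest.mark.parametrize("which", ["accel", "gyro"])
def test_riccati_fixed_point(which):
    accel, gyro = f.default_kalman_params()
    p = accel if which == "accel" else gyro
    state = KalmanState(x=np.zeros(3), P=p.R.copy())
    P_pred = None
    for _ in range(20000):
        x_pred, P_pred = f.predict(state, p)
        state = f.update(x_pred, P_pred, np.zeros(3), p)
    # fixed point satisfies the DARE (cross-checked against scipy's solver)
    A, Q, R, H = p.A, p.Q, p.R, p.H
    residual = A @ P_pred @ A.T + Q - A @ P_pred @ H.T @ np.linalg.inv(
        H @ P_pred @ H.T + R
    ) @ H @ P_pred @ A.T - P_pred
    assert np.abs(residual).max() < 1e-8
    np.testing.assert_allclose(P_pred, solve_discrete_are(A.T, H.T, Q, R), atol=1e-8)
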