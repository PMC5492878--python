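"""Synthetic trunk-worn IMU streams for six activity classes.

The generator emulates, phenomenologically, the signal signatures of a
sensor worn on the upper trunk sampling at 100 Hz:

* ``Wk`` — periodic gait (~1 Hz): bounded acceleration bounce keeping the
  resultant above 1 g, periodic angular-velocity sway.
* ``Sd`` / ``Sq`` / ``Bw`` — postural transitions: a smooth trunk-angle
  excursion that returns near upright (Bw bows transiently to ~60 deg),
  biaxial acceleration bursts, and a dominant roll-rate spike on w_x.
* ``Sd-Fall`` / ``Bw-Fall`` — the trunk angle rises from ~0 to ~90 deg in
  under 2 s, gravity migrates from the X axis into the fall plane (Y for
  sideward, Z for backward), an impact transient drives the peak resultant
  acceleration to ~2 g, and the dominant rotation axis spikes to ~200 deg/s
  (w_x sharpest for the backward fall).

Every stream is the deterministic class template (gravity projection of the
trunk-angle trajectory plus motion transients, jittered per subject and per
recording) plus stationary AR(1) sensor noise per axis, optionally topped
with white measurement noise.  Fall peaks exceed every ADL peak by
construction, in both resultant acceleration and resultant angular
velocity, so the classes are separable before any training.

A static calibration recording — the sensor at rest reading (1, 0, 0) g —
exercises the AR-identification path of :mod:`imufall.ar_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ar_model import DEFAULT_R_ACCEL, DEFAULT_R_GYRO
from .signal_features import ACTIVITY_CLASSES, DEFAULT_FS, ImuStream, write_stream_csv


@dataclass(frozen=True)
class NoiseModel:
    """Per-axis AR(1) sensor noise, plus optional white measurement noise.

    ``accel_coeff``/``gyro_coeff`` are AR(1) coefficients (|phi| <= 1),
    ``accel_sd``/``gyro_sd`` innovation standard deviations in g and deg/s.
    The measurement-noise terms default to zero; the default sensor model
    sets them from the configured R diagonals so that generated streams
    realise the same state-space model the Kalman filter assumes.
    """

    accel_coeff: tuple = (0.9974, 0.997, 0.9953)
    accel_sd: tuple = (6.573e-3, 5.743e-3, 7.337e-3)
    gyro_coeff: tuple = (0.997, 0.9269, 0.9997)
    gyro_sd: tuple = (3.464e-2, 3.162e-2, 3.317e-2)
    accel_meas_sd: tuple = (0.0, 0.0, 0.0)
    gyro_meas_sd: tuple = (0.0, 0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("accel_coeff", "gyro_coeff"):
            if any(abs(c) > 1 for c in getattr(self, name)):
                raise ValueError(f"{name}: AR(1) coefficients must satisfy |phi| <= 1")
        for name in ("accel_sd", "gyro_sd"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name}: innovation sds must be positive")
        for name in ("accel_meas_sd", "gyro_meas_sd"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValueError(f"{name}: measurement sds must be non-negative")


def default_noise_model(seed: int | None = None) -> NoiseModel:
    """The full sensor emulation: AR(1) process noise with innovation
    variances equal to the identified FPEs plus white observation noise at
    the configured R diagonals."""
    return NoiseModel(
        accel_meas_sd=tuple(float(np.sqrt(r)) for r in DEFAULT_R_ACCEL),
        gyro_meas_sd=tuple(float(np.sqrt(r)) for r in DEFAULT_R_GYRO),
        seed=seed,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path (initialised from the stationary distribution)."""
    e = rng.normal(0.0, sd, size=n)
    if abs(phi) < 1.0:
        e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    x = lfilter([1.0], [1.0, -phi], e)
    return x


def _sensor_noise(rng: np.random.Generator, n: int, noise: NoiseModel) -> tuple[np.ndarray, np.ndarray]:
    acc = np.column_stack(
        [_ar1(rng, n, noise.accel_coeff[i], noise.accel_sd[i]) for i in range(3)]
    )
    gyro = np.column_stack(
        [_ar1(rng, n, noise.gyro_coeff[i], noise.gyro_sd[i]) for i in range(3)]
    )
    for i in range(3):
        if noise.accel_meas_sd[i] > 0:
            acc[:, i] += rng.normal(0.0, noise.accel_meas_sd[i], size=n)
        if noise.gyro_meas_sd[i] > 0:
            gyro[:, i] += rng.normal(0.0, noise.gyro_meas_sd[i], size=n)
    return acc, gyro


def generate_static_calibration(
    noise: NoiseModel, duration_s: float = 120.0, fs: float = DEFAULT_FS
) -> ImuStream:
    """A resting recording: (1, 0, 0) g plus sensor noise, zero rotation."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(noise.seed)
    acc, gyro = _sensor_noise(rng, n, noise)
    acc[:, 0] += 1.0
    t = np.arange(n) / fs
    return ImuStream(t, acc, gyro, fs=fs)


# ---------------------------------------------------------------------------
# activity templates


@dataclass(frozen=True)
class ActivityTemplate:
    """Deterministic per-class signal envelope plus jitter scales.

    The trunk-angle trajectory theta*(t) drives the gravity projection
    (a_x* = cos theta*, the fall/bow plane axis carries sin theta*); motion
    is added as per-axis acceleration bursts and angular-velocity spikes;
    falls append an impact transient raising the peak resultant acceleration
    to ``impact_peak_g``.  All values are design parameters of the emulation.
    """

    label: str
    kind: str  # "periodic" | "transition" | "fall"
    duration_s: float = 5.0
    theta_base: float = 5.0  # deg, upright
    theta_peak: float = 5.0  # deg at the excursion peak (falls: ~90)
    theta_return: float = 5.0  # deg after an ADL transition
    onset_s: float = 2.0
    rise_s: float = 1.0
    hold_s: float = 0.3
    return_dur_s: float = 1.0
    plane_axis: int = 2  # 1 = Y (sideward), 2 = Z (forward/backward)
    gait_hz: float = 1.0
    theta_wobble: float = 3.0  # deg, periodic gait wobble
    bounce_g: float = 0.12
    sway_g: float = 0.05
    accel_burst: tuple = (0.0, 0.0, 0.0)  # g
    gyro_peak: tuple = (0.0, 0.0, 0.0)  # deg/s
    impact_peak_g: float = 2.0
    # an even number of sampling periods so the burst peak lies on the grid
    impact_width_s: float = 0.16
    amp_jitter: float = 0.08  # relative sd on motion amplitudes
    time_jitter_s: float = 0.10  # sd on the onset time

    def theta_trajectory(self, t: np.ndarray, time_shift: float = 0.0, freq_scale: float = 1.0) -> np.ndarray:
        """theta*(t) in degrees."""
        t = np.asarray(t, dtype=float)
        if self.kind == "periodic":
            return self.theta_base + self.theta_wobble * np.sin(
                2 * np.pi * self.gait_hz * freq_scale * t
            )
        t0 = self.onset_s + time_shift
        theta = self.theta_base + (self.theta_peak - self.theta_base) * _smoothstep(
            (t - t0) / self.rise_s
        )
        if self.kind == "transition":
            t1 = t0 + self.rise_s + self.hold_s
            theta = theta - (self.theta_peak - self.theta_return) * _smoothstep(
                (t - t1) / self.return_dur_s
            )
        return theta


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _half_sine(t: np.ndarray, start: float, width: float) -> np.ndarray:
    u = (t - start) / width
    return np.where((u >= 0) & (u <= 1), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)


def default_templates(include_stairs: bool = False) -> dict:
    """The six study classes (plus optional stair walking variants)."""
    templates = {
        "Wk": ActivityTemplate(
            label="Wk", kind="periodic", gait_hz=1.0, bounce_g=0.12, sway_g=0.05,
            gyro_peak=(10.0, 25.0, 5.0),
        ),
        "Sd": ActivityTemplate(
            label="Sd", kind="transition", theta_peak=20.0, theta_return=15.0,
            rise_s=1.2, accel_burst=(0.35, 0.05, 0.20), gyro_peak=(60.0, 15.0, 5.0),
        ),
        "Sq": ActivityTemplate(
            label="Sq", kind="transition", theta_peak=25.0, theta_return=10.0,
            rise_s=1.2, accel_burst=(0.40, 0.05, 0.25), gyro_peak=(70.0, 15.0, 5.0),
        ),
        "Bw": ActivityTemplate(
            label="Bw", kind="transition", theta_peak=60.0, theta_return=10.0,
            rise_s=1.4, accel_burst=(0.25, 0.20, 0.25), gyro_peak=(80.0, 20.0, 8.0),
        ),
        "Sd-Fall": ActivityTemplate(
            label="Sd-Fall", kind="fall", theta_peak=90.0, onset_s=2.5, rise_s=0.7,
            plane_axis=1, accel_burst=(0.30, 0.0, 0.0), gyro_peak=(60.0, 200.0, 50.0),
        ),
        "Bw-Fall": ActivityTemplate(
            label="Bw-Fall", kind="fall", theta_peak=90.0, onset_s=2.5, rise_s=0.7,
            plane_axis=2, accel_burst=(0.30, 0.0, 0.0), gyro_peak=(220.0, 60.0, 50.0),
        ),
    }
    if include_stairs:
        templates["StairUp"] = replace(
            templates["Wk"], label="StairUp", bounce_g=0.18, gyro_peak=(14.0, 32.0, 7.0)
        )
        templates["StairDown"] = replace(
            templates["Wk"], label="StairDown", bounce_g=0.22, gyro_peak=(16.0, 36.0, 8.0)
        )
    return templates


def template_envelope(
    template: ActivityTemplate,
    t: np.ndarray,
    amp_scale: float = 1.0,
    time_shift: float = 0.0,
    freq_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (acc, gyro) envelope arrays for sample times ``t``."""
    n = t.shape[0]
    theta = np.radians(template.theta_trajectory(t, time_shift, freq_scale))
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    # gravity projection of the trunk-angle trajectory (unit magnitude)
    acc[:, 0] = np.cos(theta)
    acc[:, template.plane_axis] += np.sin(theta)

    if template.kind == "periodic":
        f = template.gait_hz * freq_scale
        phase = 2 * np.pi * f * t
        acc[:, 0] += amp_scale * template.bounce_g * 0.5 * (1.0 - np.cos(phase))
        acc[:, 1] += amp_scale * template.sway_g * np.sin(phase)
        gyro[:, 0] = amp_scale * template.gyro_peak[0] * np.sin(phase + np.pi / 3)
        gyro[:, 1] = amp_scale * template.gyro_peak[1] * np.sin(phase)
        gyro[:, 2] = amp_scale * template.gyro_peak[2] * np.sin(phase + np.pi / 6)
        return acc, gyro

    t0 = template.onset_s + time_shift
    burst = _half_sine(t, t0, template.rise_s)
    if template.kind == "transition":
        for axis in range(3):
            sign = -1.0 if axis == 0 else 1.0  # downward trunk motion unloads X
            acc[:, axis] += sign * amp_scale * template.accel_burst[axis] * burst
        for axis in range(3):
            gyro[:, axis] += amp_scale * template.gyro_peak[axis] * burst
        return acc, gyro

    # fall: descent unloading, rotation-rate spike, then the impact transient
    acc[:, 0] -= amp_scale * template.accel_burst[0] * burst
    for axis in range(3):
        gyro[:, axis] += amp_scale * template.gyro_peak[axis] * burst
    t_imp = t0 + template.rise_s
    impact = _half_sine(t, t_imp, template.impact_width_s)
    acc[:, template.plane_axis] += (template.impact_peak_g - 1.0) * impact
    return acc, gyro


def generate_activity(
    template: ActivityTemplate,
    noise: NoiseModel,
    seed: int,
    fs: float = DEFAULT_FS,
    amp_scale: float = 1.0,
    time_shift: float = 0.0,
    freq_scale: float = 1.0,
    subject: int | None = None,
    jitter: bool = True,
) -> ImuStream:
    """One labelled recording: jittered template envelope plus sensor noise.

    ``amp_scale``/``time_shift``/``freq_scale`` carry subject-level jitter;
    recording-level jitter is drawn from ``seed`` using the template's
    jitter scales (disable with ``jitter=False`` for exact template
    readback)."""
    rng = np.random.default_rng(seed)
    n = int(round(template.duration_s * fs))
    t = np.arange(n) / fs
    if jitter:
        amp_scale = amp_scale * float(
            np.clip(rng.normal(1.0, template.amp_jitter), 0.6, 1.4)
        )
        time_shift = time_shift + float(rng.normal(0.0, template.time_jitter_s))
        freq_scale = freq_scale * float(np.clip(rng.normal(1.0, 0.05), 0.8, 1.2))
    # keep the event (and any fall impact) inside the recording
    max_shift = template.duration_s - template.onset_s - template.rise_s - 0.5
    time_shift = float(np.clip(time_shift, -1.0, max_shift))
    acc, gyro = template_envelope(template, t, amp_scale, time_shift, freq_scale)
    nacc, ngyro = _sensor_noise(rng, n, noise)
    return ImuStream(
        t, acc + nacc, gyro + ngyro, fs=fs, label=template.label, subject=subject
    )


def generate_dataset(
    n_per_class: int = 100,
    subjects: int = 20,
    noise: NoiseModel | None = None,
    seed: int = 17,
    templates: dict | None = None,
    fs: float = DEFAULT_FS,
) -> list:
    """A labelled corpus: ``n_per_class`` recordings per class.

    Defaults replicate the study's shape: 100 recordings for each of the six
    classes (600 total) from 20 subjects, i.e. five repetitions per subject
    and class.  Subject-level jitters (amplitude, timing, cadence) are drawn
    once per subject; every recording adds its own smaller jitter.
    Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise is None:
        noise = default_noise_model()
    if templates is None:
        templates = default_templates()
    master = np.random.default_rng(seed)
    subj_amp = np.clip(master.normal(1.0, 0.08, size=subjects), 0.7, 1.3)
    subj_time = master.normal(0.0, 0.10, size=subjects)
    subj_freq = np.clip(master.normal(1.0, 0.05, size=subjects), 0.85, 1.15)
    streams = []
    for label in templates:
        template = templates[label]
        for i in range(n_per_class):
            subject = i % subjects
            stream_seed = int(master.integers(0, 2**31))
            streams.append(
                generate_activity(
                    template,
                    noise,
                    seed=stream_seed,
                    fs=fs,
                    amp_scale=float(subj_amp[subject]),
                    time_shift=float(subj_time[subject]),
                    freq_scale=float(subj_freq[subject]),
                    subject=subject,
                )
            )
    return streams


def write_dataset(streams, directory) -> None:
    """Write a corpus as one CSV per stream plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict = {}
    for stream in streams:
        label = stream.label or "unlabelled"
        k = counters.get(label, 0)
        counters[label] = k + 1
        name = f"{label}_{k:03d}.csv"
        write_stream_csv(stream, directory / name)
        rows.append({"file": name, "label": label, "subject": stream.subject})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
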