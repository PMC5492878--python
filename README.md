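# imufall

Wearable-IMU fall detection for a trunk-worn sensor: Kalman denoising of
tri-axial accelerometer/gyroscope streams parameterised by an autoregressive
noise model, trunk-angle and resultant-magnitude features, 2 s sliding-window
segmentation, and naive-Bayes / Bayes-network classification of six activity
classes — four activities of daily living (walking `Wk`, sitting down `Sd`,
squatting down `Sq`, bowing `Bw`) and two falls (sideward `Sd-Fall`,
backward `Bw-Fall`).

It is aimed at researchers in inertial human-activity recognition who want a
tested, scriptable reference pipeline, including a synthetic activity
simulator so everything runs without sensor hardware or proprietary
recordings.

## The model

A sensor on the upper trunk samples tri-axial acceleration *a(t)* (in g) and
angular velocity *ω(t)* (in deg/s) at 100 Hz, with X the trunk's
longitudinal axis. Per sample the pipeline derives

- resultant acceleration  a(t) = √(a_x² + a_y² + a_z²),
- trunk angle  θ(t) = arccos(a_x / a(t))  — ≈0° standing, ≈90° lying,
- resultant angular velocity  ω(t) = √(ω_x² + ω_y² + ω_z²).

Sensor noise is identified from a 2 min static recording: AR(p) models
(p = 1..3) are fitted per axis and compared by Akaike's final prediction
error, FPE = σ̂²(n+p+1)/(n−p−1); AR(1) wins on every axis. The AR(1)
coefficient and FPE supply the diagonals of the Kalman state-transition
matrix A and process covariance Q; the measurement covariance R is
configured. The filter runs the standard predict/update recursion

    x(k|k−1) = A x(k−1|k−1)               P(k|k−1) = A P A' + Q
    Kg = P(k|k−1) H' (H P(k|k−1) H' + R)⁻¹
    x(k|k) = x(k|k−1) + Kg (z − H x(k|k−1)),  P(k|k) = (I − Kg H) P(k|k−1)

independently over the acceleration and gyro channels (H = I, no control
input). Since a fall lasts under 2 s, features are segmented by a 200-sample
sliding window. A Bayes-network classifier B = ⟨G, Θ⟩ with the class node as
root factorises P(C, X₁..X_d) = P(C)·∏ P(X_i | C, π_i); structure is learned
by greedy hill-climbing under a decomposable Dirichlet score on
equal-frequency-binned features, and windows are labelled by the
window-averaged log posterior. Evaluation is stratified 10-fold
cross-validation at the recording level, reporting six-class accuracy plus
fall-vs-ADL sensitivity and specificity.

## Worked example

```python
import imufall as fd

data = fd.generate_dataset(n_per_class=20, subjects=5, seed=17)
table, report = fd.cross_validate(data, fd.PipelineConfig(), k=5, seed=17)
print(table.to_frame())
print(f"accuracy    : {report.accuracy_6class:.4f}")
print(f"sensitivity : {report.sensitivity:.4f}")
print(f"specificity : {report.specificity:.4f}")
```

prints

```
         Wk  Sd  Sq  Bw  Sd-Fall  Bw-Fall
Wk       20   0   0   0        0        0
Sd        0  14   6   0        0        0
Sq        0   3  17   0        0        0
Bw        0   0   0  19        0        1
Sd-Fall   0   0   0   0       20        0
Bw-Fall   0   0   0   0        0       20
accuracy    : 0.9167
sensitivity : 1.0000
specificity : 0.9875
```

Rows are true classes, columns predictions over the 120 held-out
recordings. Both falls are always recognised as falls (sensitivity 1.0);
the six-class errors are mostly the physically similar sit-down/squat pair,
and one bow mistaken for a backward fall costs a little specificity.

The same pipeline is scriptable from a shell:

```sh
imufall simulate --out corpus --n-per-class 20 --subjects 5 --seed 17
imufall calibrate corpus/calibration.csv --out cal.txt
imufall train corpus --out model.json
imufall classify corpus/Bw-Fall_000.csv --model model.json   # -> Bw-Fall
imufall evaluate corpus --ablation features
```

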