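# Methods

## Pipeline model and assumptions

The system treats trunk-worn IMU output as a linear stochastic process
observed with noise. Six activity classes are modelled: walking (`Wk`),
sitting down (`Sd`), squatting down (`Sq`), bowing (`Bw`), sideward fall
(`Sd-Fall`) and backward fall (`Bw-Fall`). The trunk frame is fixed with X
longitudinal, so a standing, resting accelerometer reads ≈(1, 0, 0) g and
the trunk angle θ = arccos(a_x/‖a‖) is ≈0° upright and ≈90° lying. θ is a
gravity-direction estimate, valid when body acceleration is small relative
to gravity; during the fall impact itself it is transiently unreliable,
which is why classification uses the whole 2 s window rather than a single
sample. No quaternion/orientation tracking is attempted: θ is the only
orientation estimate.

Each tri-axial channel (acceleration; angular velocity) is filtered by an
independent 3-state Kalman filter with diagonal A, Q, R and H = I, i.e. six
independent scalar filters. The state model is AR(1) per axis, identified
from a static calibration recording; the filter therefore denoises toward
the slowly varying sensor-plus-gravity level and removes fast measurement
jitter. The ordering is filter first, then derive features: resultant
magnitudes and trunk angle are computed from the filtered axes (a raw-path
switch exists for A/B comparison, `PipelineConfig(use_kalman=False)`).

## AR identification and Kalman parameters

- Estimation: ordinary least squares of x_t on its p lags after mean
  removal, no intercept (conditional maximum likelihood). Yule–Walker (via
  statsmodels) is available as a config alternative; differences are
  O(1/n). Mean removal matters because accelerometer axes carry a gravity
  offset: an AR model of a non-centred near-unit-root series is ill-posed.
  The removed mean is carried into the filter as a state offset and added
  back on output.
- Model order: Akaike's FPE = σ̂²(n+p+1)/(n−p−1) over p ∈ {1, 2, 3}. The
  selection rule takes the lowest order whose FPE is within a relative
  factor (default 2×) of the best candidate, because higher orders shave
  only marginal amounts off the FPE of static sensor noise; on the default
  synthetic calibration this selects AR(1) on all six axes.
- Kalman assembly: A = diag(a₁ per axis), Q = diag(FPE per axis) with no
  rounding, H = I, B·U ≡ 0. R is a configuration input, defaulting to
  diag(2e−5, 2e−5, 3e−5) g² for acceleration and diag(2e−3, 8.7e−4,
  1.09e−3) (deg/s)² for the gyro; no derivation of R from data is
  attempted. a₁ = 1 (random-walk state) is permitted without special
  casing.
- Initialisation: x₀ = first measurement, P₀ = R. This avoids a start-up
  transient and makes a constant stream an exact fixed point when A = I (or
  when the stream rests at the state offset). Covariances are
  re-symmetrised each step as (P + Pᵀ)/2; the Joseph-form update is not
  used. Every gain diagonal lies in [0, 1) because R ≻ 0.

## Features, windows and the classifier

Three feature sets are supported per sample: FS9 (three acceleration axes,
resultant acceleration, three gyro axes, resultant angular velocity, trunk
angle), FS7 (raw axes + trunk angle) and FS3 (the derived triple only).
Windows are 0-based, half-open [start, start+width) with width = round(fs ×
seconds); the default 2 s at 100 Hz gives 200 samples, matching the premise
that a fall completes within 2 s. Deployment-style sliding uses step = 1;
training and evaluation instead use **one event window per recording**,
centred on the peak resultant angular velocity: labelling the quiet lead-in
samples of a fall recording as "fall" would inject label noise, and
counting near-duplicate step-1 windows as independent instances would
overstate n.

Naive Bayes uses per-class Gaussian likelihoods on continuous features
(variances floored at max(1e−9 × pooled variance, 1e−12) so degenerate
constant features cannot produce infinite densities). The Bayes network
discretises features by equal-frequency binning (default 10 bins; duplicate
quantile edges merged), estimates CPTs by maximum likelihood with Laplace
smoothing α = 0.5, and learns structure by greedy hill-climbing: starting
from the naive (class-parent-only) graph, the edge with the largest
positive gain in the Dirichlet(α) log marginal likelihood (K2-style,
decomposable) is added, each feature node accepting at most one feature
parent on top of the class node (the classic class-rooted tree-augmented
shape; the CPT layout supports exactly one feature parent, so
`max_parents > 1` is rejected). The search is deterministic; the `seed`
argument exists for interface stability. Values outside the learned bin
range fall into the edge bins, so no instance ever has zero likelihood.

All posterior computation is in log space (an FS9 window multiplies 1800
factors). Window aggregation is either majority vote over per-sample argmax
labels or the argmax of the window-averaged log posterior (default — it
uses the full posterior rather than only the votes). Ties break toward the
fall classes, then lexicographically: in a safety application a tie must
alarm.

## Evaluation

Cross-validation is stratified at the recording level (per-class fold
counts differ by ≤1); a recording never contributes samples to both sides
of a fold. Metrics from the pooled confusion table: six-class accuracy
(trace/total — fall subtypes confused with each other count as errors);
sensitivity = fraction of true falls predicted as *any* fall class;
specificity = fraction of true ADLs predicted as any ADL class; the
fall-vs-ADL binarisation's TP/FP rates are sensitivity and 1 − specificity.
These binarised definitions are the only ones under which sensitivity can
exceed every per-subtype accuracy, which is how headline detection numbers
are conventionally reported for this task. Ablations (feature sets; filter
on/off) reuse identical fold assignments so differences are attributable to
configuration alone. A structural comparison against stock scikit-learn
baselines (k-NN, Gaussian naive Bayes, decision tree, Bagging) operates on
per-window summary statistics; its wall-clock column is descriptive only.
No inferential testing is performed; reports are descriptive.

## The synthetic generator

The generator emulates the *statistical signatures* of the six classes, not
their biomechanics (no multi-segment rigid-body model). Each recording is 5
s at 100 Hz (all recordings the same length): a deterministic class
template plus noise.

- Template = gravity projection of a trunk-angle trajectory θ*(t)
  (a_x* = cos θ*, the fall/bow plane axis carries sin θ*, so the noiseless
  resultant is exactly 1 g in quasi-static segments) plus motion
  transients. Walking is periodic at ≈1 Hz with a non-negative bounce
  (resultant never below 1 g); Sd/Sq/Bw are smoothstep excursions that
  return near upright (Bw bows transiently to 60°) with a dominant ω_x
  spike of 60–80 deg/s; falls rise to 90° in 0.7 s with a ≈200 deg/s
  rotation spike (ω_x sharpest for the backward fall, the class's characteristic
  signature) and a half-sine impact raising the peak resultant to
  2 g. The impact width is 0.16 s — an even number of sampling periods, so
  the sampled burst peak equals the nominal impact parameter exactly. All
  template numbers are design parameters of the emulation; fall peaks
  exceed every ADL peak in both resultant acceleration and angular
  velocity by construction, so the classes are separable before training.
- Noise = stationary AR(1) per axis (initialised from the stationary
  distribution) plus optional white measurement noise. The *default sensor
  model* uses AR coefficients ≈0.997–0.9997, innovation variances equal to
  the identified FPE diagonals and measurement noise at √R — i.e. exactly
  the state-space model the Kalman filter assumes, which is what a
  faithfully emulated sensor should produce and what makes the
  with/without-filter comparison meaningful. Printed unit-root coefficients
  (a₁ = 1) are replaced by 0.997 in generator defaults, since a random
  walk drifts unboundedly over a 2 min calibration; the fitting code still
  accepts a₁ = 1.
- Jitter: per-subject amplitude (σ = 8%), timing (σ = 0.1 s) and cadence
  (σ = 5%) multipliers, plus smaller per-recording jitter, all seeded;
  corpus generation is byte-identical under a fixed seed. The default
  corpus is 100 recordings per class from 20 subjects (600 total, five
  repetitions per subject and class). Stair-walking templates exist as
  optional extras, off by default.

What passing tests on this corpus demonstrate: the pipeline's machinery —
calibration, filtering, feature extraction, windowing, training, inference
and the evaluation arithmetic — is correct, and the expected orderings
(more features ≥ fewer; filtered ≥ raw) hold under paired folds. What they
do **not** show: performance on real human falls. Real recordings contain
inter-subject variability, soft-tissue and garment artefacts, unmodelled
ADLs and impact dynamics far richer than a half-sine; headline accuracies
measured on human-subject data are properties of those data and are not
reproduced by simulation.

## Problem sizes and runtime choices

Defaults were chosen so a full desk run is comfortable on one CPU: 600
recordings × 500 samples for the end-to-end evaluation (≈15 s including
both ablations), 12 000-sample calibrations, and n = 20 000 series for AR
recovery checks (coefficient standard error ≈ 7e−4 at φ = 0.99). The scalar
Kalman recursion is a plain-float loop per axis, verified to machine
precision against the matrix predict/update implementation.

## Known limitations

- The trunk angle conflates body acceleration with gravity during dynamic
  phases; only window-level aggregation mitigates this.
- The Bayes network supports at most one feature parent per node.
- Falls are modelled as single-impact events; syncope-style slow collapses
  or recovered stumbles are not in the template set.
- The evaluation treats each recording as one event; continuous-stream
  deployment (step-1 sliding with alarm debouncing) is exposed by the API
  (`slide`, step = 1) but not separately benchmarked.
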