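# Methods

This note documents the model implemented by `rehabfis`, the synthetic data
that exercises it, the numerical choices, and their limitations.

## Problem framing

Five upper-limb range-of-motion exercises (shoulder flexion–extension,
horizontal abduction–adduction, elbow external–internal rotation, forearm
pronation–supination, wrist ulnar–radial deviation) are performed on a rigid
schedule: rest 2 s → move 4 s → rest 2 s → move 4 s, five 12-second cycles.
Because the schedule is known, supervision is free: each sample is labeled
with a number from its scheduled motion's half-open label range, and
recognition is regression of that label from inertial features followed by
range decoding. Labels are assigned at the *midpoint* of each range by
default — any in-range number decodes identically, and the midpoint maximizes
the margin to both decision boundaries; `ramp` and seeded `uniform` modes are
available for robustness experiments. The pronation–supination schedule keeps
its published label ranges verbatim, which leave `[14, 15)` unused; ranges
only need to be disjoint, and they are plain schedule data that callers can
override.

## Synthetic motion model

The simulator treats each exercise as one rotational degree of freedom: a
tilt angle θ(t) about a single sensor axis follows the schedule (rests hold
θ, movements ramp between the two rest postures). Movement ramps default to
a smoothstep profile, which has zero endpoint velocity and therefore no
gyroscope discontinuities at motion changes; a linear profile is available.
The accelerometer reads unit gravity rotated into the sensor frame
(`(0, sin θ, cos θ)` for rotations about x; `(cos θ, sin θ, 0)` about z), and
the gyroscope reads the analytic derivative of θ on the exercise's rotation
axis — rest segments therefore have exactly zero angular velocity before
noise. Gaussian noise is added per channel, 0.02 g and 1 deg/s by default: a
plausible consumer-IMU scale, configurable. For pronation–supination the
angle is observed about x while the rotation rate registers on the gyro's y
axis, reflecting a wear orientation with the forearm along the sensor's y
axis; this keeps the exercise's published feature pair (rANGVy, rANGx)
meaningful. A fixed seed makes streams bit-reproducible, and the sample count
is `floor(duration × frequency)` with frequency restricted to the sensor's
20–100 Hz range.

What the simulator does *not* model: translation dynamics and movement
accelerations (accelerometers at slow rehabilitation speeds are
gravity-dominated, and the recognition features are angles and angular
velocities), tremor and non-stationary noise, gyro drift, soft-tissue
artifacts, or a subject deviating from the schedule. Passing tests on this
data therefore demonstrates correctness of the modeling chain under its own
assumptions — schedule-following motion with stationary sensor noise — not
recognition performance on real patients. The outlier injector perturbs a
chosen fraction of gyro samples far beyond any trained membership support, so
downstream outlier handling is testable, but it is not a model of real
misuse.

## Feature extraction

Tilt follows the gravity-referenced convention `rANGx = atan2(ay, az)`,
`rANGy = atan2(-ax, hypot(ay, az))`, `rANGz = atan2(ay, ax)`; the z tilt
reads the gravity direction projected on the sensor's x–y plane, the
observable quantity for motions performed with z horizontal (wrist
deviation). A zero-magnitude acceleration raises — a free-falling sensor has
no gravity reference. Angles are unwrapped along time (period 360°) and then
shifted by whole revolutions so the series' midrange lands in (−180°, 180°];
this keeps the flexion–extension sweep on [−180°, 0°] regardless of which
side of the ±180° branch the first noisy sample happens to fall on. Angles
are reported in the body-neutral reference (arm overhead ≈ 0°, hanging
≈ −180°); an option re-references them to the calibration instant instead.
The calibration origin is the per-axis mean over the initial 0.5 s rest
window and supplies the gyro bias and acceleration offset for rANGV and rACC.
Angular velocity is the bias-corrected gyroscope reading itself, not a
differenced angle.

An alternative design would integrate the gyroscope for the angle feature;
accelerometer tilt was chosen because it is drift-free and consistent with
the observed feature ranges, and the round-trip test (simulate → features
recovers the generating trajectory to < 0.5°) pins the convention down.

Complex exercises merge the labeled tables of sub-exercises over the union of
their (required-disjoint) feature sets; features a row's sub-exercise does
not use carry the sentinel −999, which inference and training treat as
"masked": sentinel inputs belong to no fuzzy set of their variable and
contribute nothing to linear consequents or gradients.

## Fuzzy system design

The initial system is built from per-motion feature statistics of the labeled
sample data:

* velocity input — one triangle shared by the rest motions, centered on the
  pooled rest readings with half-width `max(3σ, 5% of span)`, plus one
  trapezoid per movement spanning that movement's 10–90% quantiles with 10%
  padding;
* angle input — one triangle per rest posture, plus a single trapezoid over
  the pooled movement range (both movement directions traverse the same
  angles; the velocity input separates them);
* output — one triangle per motion, centered in its label range with
  half-width 1, so its area centroid is exactly the range midpoint.

This yields the published 3 × 3 structure for the two-feature exercises. The
Mamdani design uses the classical min t-norm; `mam2sug` converts output MFs
to constant (zero-order) consequents at their centroids and switches to the
product t-norm, the differentiable choice hybrid training requires.
`grid_complete` fills the 3 × 3 − 4 = 5 missing antecedent combinations with
dummy rules whose consequents are spaced through the virtual label range
[−0.5, 0); dummy rules stay in the rule base and participate in inference —
real data simply never lands on their combinations, and anything that decodes
into the virtual range is reported as such.

Mamdani inference uses min implication, max aggregation, and a discrete
centroid computed with trapezoid-rule integration over a 1001-point grid
(configurable; 1001 vs 10001 points differ by ~10⁻⁶ on systems of this
shape). Sugeno inference is the standard weighted average. In both flavors a
zero total firing (≤ 10⁻¹²) yields NaN — the outlier flag — not an exception.

## Hybrid training

Each epoch solves the consequents globally by ridge-regularized least squares
(ridge 10⁻⁸ keeps rarely-fired dummy rules well-conditioned) on the
firing-strength-normalized design matrix, then takes one analytic gradient
step on the premise parameters through the chain rule of the weighted
average. Constant consequents are upgraded to first-order linear ones
(slopes 0, intercept = constant) before training. Triangle and trapezoid
derivatives use the one-sided (left) convention at kinks, and the parameter
ordering constraint is re-imposed by projection (sorting) after each step;
gaussian widths are floored at 10⁻⁶. The step size (default 0.01) adapts in
Jang's style: ×1.1 after four consecutive error decreases, ×0.9 after two
oscillations. Training stops at the epoch budget, when the RMSE falls below
`tol` (10⁻⁶), or when it varies by less than `tol` over five epochs; an RMSE
exceeding ten times its initial value aborts with a diagnostic (the guard is
skipped when the fit is already essentially exact). Training has no hidden
randomness: identical inputs give identical results. Because the RMSE
gradient does not vanish at a perfect fit (RMSE is a norm), the below-`tol`
stop matters: without it a final gradient step would perturb an exact
solution.

One identifiability note: when the premises differ slightly from a generating
system's, least squares compensates with adjusted consequent planes, so
coefficient-wise comparisons to the generator are only meaningful when the
premise structure is planted exactly; predictive RMSE is the right metric
otherwise. The parameter-recovery experiment therefore plants the premises
and recovers the consequents.

The epoch defaults used by the bundled workflow (30 epochs for the synthetic
exercises, 50 for the recovery experiment) sit well past the point where the
RMSE trace flattens on these problems.

## Evaluation schemes

* **Adaptable**: a sample is correct if it decodes to its scheduled motion,
  or if it lies in the first (last) 10% of its segment and decodes to the
  temporally previous (next) motion, cyclically across the cycle boundary.
  "10%" is read as a share of each motion's samples. This rate dominates the
  strict rate by construction.
* **Quartile**: each segment is cut at its 25/50/75% sample positions
  (`n//4` and `n - n//4`); the 25% set is the first quarter, the 50% set the
  central half, the 75% set the last quarter, scored strictly and pooled
  over cycles. The three sets partition the segment, so their
  sample-weighted average equals the strict rate. Segments with fewer than 4
  samples are skipped with a warning. The alternative reading — four equal
  quarters reported at their cuts — was rejected because the outer sets are
  meant to isolate motion changes, which requires the central half to be one
  contiguous set.
* **Grade**: level 1 for rate ≥ 0.8, then 0.2-wide bands down to level 4 at
  [0.2, 0.4), level 0 (failed) below 0.2; a motion is confirmed when its
  rate exceeds 0.4. The bands are made exhaustive this way because the
  verbal description ("level 4 is less than 20%, level 0 is failed")
  overlaps at the bottom.
* **Confusion**: decisions are one per second — the median inferred label
  over the central 50% of that second's samples (medians are robust to a few
  boundary samples; an all-outlier center yields an outlier decision). A
  decision is positive when its scheduled motion belongs to the target
  exercise's label ranges, predicted positive when its label falls in those
  ranges and, by default, decodes to the scheduled motion (a flag relaxes
  this to any in-range label). Outlier decisions count against the system —
  FN when scheduled positive, FP otherwise — so TP+FN+FP+TN always equals
  the number of decisions.

Outliers are counted as errors in all schemes.

## Serialization

The canonical fuzzy-system format is a versioned JSON schema (variables, MF
shapes and parameters, rules with antecedent indices, consequents, dummy
flags, metadata including the exercise id, feature names and virtual
sentinel). Validation is strict and reports JSON-pointer-style paths. An
FLL-style text export is provided for interoperability with fuzzy-logic
tooling; it is write-only. CSV formats are UTF-8, comma-separated,
dot-decimal with a mandatory header and a units comment line; floats are
written at 17 significant digits and parsed with round-trip precision, so
write∘read is exact. Readers reject malformed input (wrong columns,
non-monotone timestamps) with the offending line number rather than coercing.

The packaged fixture `flex_ext_table3.json` ships the published trained
flexion–extension system verbatim (3+3 input MFs, 4 real + 5 dummy rules
with first-order consequents). Its structure is load-bearing for tests; its
trained coefficients are carried as data only — read at face value over the
printed MF ranges they do not map inputs into the label ranges, so only
structural and single-rule properties are asserted about them.

## Known limitations

* Single-axis kinematics: exercises that genuinely mix rotation axes are out
  of scope of the simulator (though the feature pipeline handles arbitrary
  streams).
* The y-axis tilt formula spans only (−90°, 90°), so simulated exercises
  rotate about x or z; no built-in exercise needs a y-angle feature.
* Premise gradient training supports triangle, trapezoid and gaussian MFs;
  the other shapes evaluate but cannot be trained.
* Mamdani systems are inference-only; training always goes through the
  Sugeno conversion.
* Real-sensor concerns — BLE transport, resampling irregular timestamps,
  magnetometer fusion — are explicitly not addressed.
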