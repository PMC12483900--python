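# Methods

## The kinematic model

The simulator drives a planar two-link leg with a crank. The pedal spindle
moves on a circle of radius `crank_length` (default 170 mm) around the
bottom bracket; crank phase φ is 0° at top dead center (TDC) and increases
in the pedaling direction, so bottom dead center (BDC) is 180°. The hip
joint sits up the seat tube: `hip = bb + saddle_height · (−cos α, sin α)`
with seat-tube angle α (default 73° from horizontal, x forward, z up).
The ankle joint is `ankle_pedal_offset` (default 80 mm) above the pedal.

Sagittal hip and knee angles come from law-of-cosines inverse kinematics on
the hip–ankle distance *d*:

    knee_flexion = 180° − arccos((t² + s² − d²) / (2·t·s))

with thigh *t* and shank *s*, knee-forward branch always; hip flexion is the
thigh's angle from the straight-down trunk reference. Forward kinematics of
the returned angles reproduces the ankle target to < 1e−9 mm (tested on
10⁴ random configurations).

**Effective segment lengths.** Saddle height is set as a fraction of the
rider's greater trochanter height (GTH): low = 0.95, moderate drawn once
per ride from U[0.97, 1.03], high = 1.05. Reaching a saddle at ~GTH plus a
crank length is only possible for a human because the plantarflexed foot
extends the leg at BDC. A strict thigh+shank chain (≈0.94·GTH) cannot
reach; the model therefore uses *effective* link lengths that fold the foot
lever into the distal link: thigh = 0.64·GTH, shank = 0.60·GTH (each with
2% multiplicative inter-subject noise, GTH ~ Normal(880, 45) mm truncated
at ±2 SD). This yields TDC knee flexion ≈ 108° and BDC knee flexion ≈
65/55/45° at the low/moderate/high levels — plausible dynamic values with
the correct monotonicity: minimum knee flexion decreases, and sagittal knee
ROM increases, as the saddle rises.

The static bike-fit rule is available as an inverse problem:
`solve_saddle_for_bdc_knee_angle` bisects the monotone saddle → BDC-knee
map to the height giving a requested knee flexion (e.g. the classical
25–35° window) to within 0.01°.

## What the generator emulates

One ride = `n_cycles` crank revolutions at `cadence_rpm` (default 80) with
per-cycle cadence jitter (SD 1 rpm), sampled at 250 Hz, padded by half a
cycle on each side so all n_cycles+1 TDC maxima of the RANK (lateral
malleolus) marker's z-coordinate are interior to the record.

* **Sagittal channel (geometry-driven).** Hip/knee from IK; ankle from a
  one-harmonic ankling model, mean 10° and amplitude 15°, the amplitude
  shrinking slightly with saddle height (−12°/unit GTH-fraction) and the
  mean rising (+15°/unit) — riders point the toe more on a high saddle.
* **Out-of-plane channel (phenomenological).** The six coronal/transverse
  components are sinusoids (mean 5°, amplitude 2°, fixed per-component
  phases) plus Gaussian noise whose SD grows with saddle height:
  SD = 1.0° + 6.5°·(gth_fraction − 1). A high saddle exacerbates
  out-of-plane oscillation; a low saddle steadies it. The slope is set so
  that each out-of-plane SD feature is individually *less* informative than
  the sagittal knee features while the six of them jointly carry strong,
  rider-invariant class signal — the structure that lets subject-held-out
  classification succeed.
* **Rider idiosyncrasy.** Each subject draws a style: ankle-mean offset
  (SD 3°), ankle-amplitude offset (SD 0.3°), per-component out-of-plane
  mean offsets (SD 2°) and phase offsets (SD 15°). These persist across
  that subject's three rides, which is what makes leave-one-subject-out
  evaluation meaningfully harder than random-fold evaluation.
* **Cycle-to-cycle variability.** Every cycle draws one offset per
  component (sagittal SD 1.5°, out-of-plane SD 1.0°) shifting the whole
  cycle — no rider repeats a revolution exactly. Per-sample measurement
  noise (SD 1° on angles, 0.5 mm on the marker) sits on top.

What it does **not** emulate: muscle dynamics and forces, pelvic rocking,
fatigue drift within a ride, marker dropout/relabeling, soft-tissue
artifact structure, or 3-D linkage coupling between the planes (the
out-of-plane components are statistically, not mechanically, linked to the
crank). Passing tests therefore demonstrate that the *pipeline* recovers
structure a real study reports, not that the generator reproduces real
Vicon data.

## Pipeline choices

* **Filtering.** Zero-lag 4th-order Butterworth, 6 Hz cutoff, applied
  forward–backward (`filtfilt`), so the effective gain at the cutoff is
  |H|² = 1/2. Only the marker trajectory is filtered by default; a flag
  extends filtering to the angle series.
* **Cycle detection.** Local maxima of the filtered z-coordinate with
  minimum separation 60/130 rpm and prominence ≥ 10% of the signal's
  peak-to-peak range; consecutive maxima delimit cycles; edge samples
  outside the first/last maximum are discarded.
* **Outlier cycles.** Excluded iff duration deviates > 20% from the median
  cycle duration, or any angle magnitude exceeds 200°; both thresholds
  configurable, each exclusion logged with its rule.
* **Crank phase.** No crank encoder exists in the data model, so phase is
  linear within each cycle: 360°·i/n, 0° at the starting z-maximum.
* **Feature conventions.** SD is the sample (n−1) estimator; CV = SD/|Mean|
  (dimensionless, NaN below |Mean| < 1e−9, logged); argmax/argmin ties take
  the earliest crank phase. Normalization divides by the per-column maximum
  *absolute* value so signed angles stay in [−1, 1]; in strict evaluation
  the divisors come from the training fold only.
* **SMOTE.** k = 5 neighbours, Euclidean on normalized features, synthetic
  rows flagged and carrying their base row's subject id. Implemented
  in-package (interpolation between same-class nearest neighbours) and
  property-tested for convexity.
* **Selection.** Greedy forward search scored by 5-fold stratified CV
  misclassification of a KNN wrapper (k = 5); ties break to the lowest
  column index; stop when the best improvement is < 1e−4 or 20 features are
  reached. Each greedy step is tested against an exhaustive scan oracle.
* **Classifiers.** SVM (RBF, C = 1), KNN (k = 5, Euclidean), Gaussian NB,
  decision tree (gini, depth ≤ 10 — a bounded default in lieu of per-run
  tuning). Optional hyperparameter search: a Gaussian-process
  expected-improvement optimizer over log-scaled bounded spaces (budget 30
  evaluations, ~1/3 random initialization), checked against a grid oracle.
* **Statistics.** Friedman on within-subject ranks (average ranks on ties,
  no extra tie correction), χ² reference with k−1 df; the unit of analysis
  is the per-subject per-level mean (n = 16, k = 3) — testing thousands of
  cycles as if independent would pseudo-replicate, though the cycle-level
  table is available. Wilcoxon signed-rank post-hocs drop zero differences,
  use the exact null up to 25 non-zero pairs and the continuity-corrected
  normal above, and multiply p by 3 (the number of level pairs), capped at
  1. Pearson categories: strong |r| ≥ 0.7, moderate ≥ 0.5, low ≥ 0.3,
  negligible below — left-inclusive boundaries.

## Evaluation modes and leakage

`paper` mode normalizes and SMOTE-balances the full table before the
subject-wise split, replicating the common (and leakage-prone) ordering:
synthetic rows interpolate across what later become test subjects. `strict`
mode fits scales and SMOTE inside each training fold. Across cohort seeds
the strict-mode mean LOSOCV accuracy does not exceed the paper-mode mean;
the package reports both on request, and the direction is asserted as a
tendency over ≥ 10 seeds, not per seed.

## Problem sizes and determinism

The default synthetic study is 16 subjects × 3 rides × 30 cycles
(≈ 1,440 cycles, ≈ 5.7 × 10³ samples per ride); a real 2-minute ride at
80 rpm would hold ~160 cycles, and the pipeline scales linearly if asked
for it. All randomness flows from one root seed through
`numpy.random.default_rng` seed sequences (per subject, per level, per
stage), so a config re-run reproduces every artifact bitwise.

## Known limitations

* The out-of-plane components are statistically tied to saddle height, not
  mechanically derived; their SD slope is a modelling assertion.
* The moderate band is drawn per ride, so a cohort can by chance contain
  moderate rides hugging a band edge; cohort-level qualitative outcomes
  (which feature family ranks first, per-model class ordering, absolute
  accuracy) then fluctuate across seeds. On the canonical seed the expected
  structure holds; across eight seeds examined it holds for most but not
  all.
* Classification accuracy in `paper` mode inherits the leakage of that
  ordering and should not be read as an unbiased generalization estimate —
  that is what `strict` mode is for.
* CV features are undefined for zero-mean components and reported as NaN;
  the default generator keeps all component means away from zero.
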