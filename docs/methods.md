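# Methods

This note documents the models, conventions and design choices behind
`pallidomap`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic experiments do and do not demonstrate.

## Scores

The Normalized Bradykinesia Score (NBS) is the mean of the rated
MDS-UPDRS III bradykinesia subitems (items 3.4–3.8; finger tapping, hand
movements, pronation/supination, toe tapping, leg agility). Normalizing by
the number of rated items makes scores comparable when video material only
allows a subset of items to be rated. Subitem scores are accepted in
half-point steps (0, 0.5, …, 4): real rating tables print half-point sums,
and a strict integer rule would reject them. The Bradykinesia Difference
Score BDS = NBS_post − NBS_pre is the change metric; *any* strictly
positive BDS counts as worsening (BDS = 0 does not). Neither score is a
validated clinical instrument; they are normalization devices.

Responder categories for dystonia improvement use left-closed upper bins:
non (< 25%), average (25–50%), good (50–80%), super (≥ 80%). The boundary
assignment (0.80 → super) is a convention; flip it by adapting
`responder_category` if a different reading is needed.

TEED (total electrical energy delivered per second) is I²·R·pw·f·1 s in µJ.
Current-controlled stimulators report no impedance, so `teed()` demands an
explicit impedance argument — there is no hidden 1 kΩ default outside the
reprogramming tie-break, where a nominal 1000 Ω is set in `SearchSpace` and
only orders energetically equivalent candidates.

## Kinematics

Signals: thumb–index fingertip distance normalized to the per-frame thumb
chain length (median across frames) for finger tapping; the interior angle
at each finger's MCP joint (wrist–MCP–fingertip, degrees) for hand opening,
plus the four-finger mean. Both are scale-free, so features are invariant
to camera zoom — the normalization contract the tests enforce. No depth
correction is attempted: out-of-plane movement can bias 2D speed and
amplitude, a known limitation of single-camera kinematics.

Cycle detection runs on a low-pass filtered copy (4th-order zero-phase
Butterworth, 6 Hz cut-off — hand tapping lives at 1–4 Hz) with peak
prominence ≥ 0.15 × the robust (5th–95th percentile) signal range; features
are measured on the raw signal. Cycles are consecutive peak-to-peak spans;
the excursion is peak value minus the minimum between peaks.

Features: frequency = cycles / (last-peak time − first-peak time);
amplitude = mean per-cycle excursion; speed = mean |dv/dt| (central
differences) over the cycling window; amplitude and velocity decay = the
least-squares slope of per-cycle excursion (or per-cycle peak |dv/dt|)
against cycle index, divided by the first cycle's value — a fraction per
cycle, negative for decrementing movements (the parkinsonian sequence
effect). Decays need ≥ 3 cycles and are left unset below that. All
thresholds live in `KinematicsConfig`.

## VTA model

The spherical parametric model r(A, pw) = k₁·√A·(pw/60 µs)^k₂, clamped to
[0, 6] mm (defaults k₁ = 1.5 mm, k₂ = 0.3), deliberately replaces
finite-element field modelling. The downstream analysis only consumes two
properties — where stimulation is, and that activation volume grows
monotonically with amplitude and pulse width — and the parametric model
preserves exactly these. Multi-contact configurations would form unions of
spheres; a sub-half-voxel radius still activates the nearest voxel so every
programmed setting has a non-empty VTA. Left-hemisphere VTAs are mirrored
through the midsagittal plane (x → −x in MNI RAS) and pooled on a single
0.5 mm isotropic right-hemisphere grid, doubling per-voxel sample sizes;
mirroring is a switch (`patient_vta(..., mirror_left=False)`) for
hemisphere-separate analyses.

Coordinate conventions: 0-based voxel indices, the affine maps indices to
*voxel centres* in MNI mm, and volumes entering one computation must share
shape and affine exactly — violations raise, nothing is resampled silently.

## Voxelwise mapping

At every voxel with ≥ `min_group` (default 5) patients on each side of the
covered/uncovered split, a pooled-variance two-sample t-test (Welch
optional) compares severity; t > 0 means stimulated-worse. Clusters are
26-connected components of voxels with uncorrected p < 0.05 and the
polarity-matching sign; components must exceed 500 voxels (strictly) to
survive. The spot weight is |t| inside surviving clusters and 0 elsewhere
for both polarities, so that patient scores (mean weight over the VTA) read
"larger = stronger association" for sour and sweet maps alike; a (1 − p)
weighting is available via `MappingConfig.weight_kind`.

This cluster rule — uncorrected voxel p with a size threshold — controls
neither voxel- nor cluster-level family-wise error. The test-suite
*measures* the map-wise null cluster rate over 100 no-effect cohorts and
keeps it under an empirical design bound of 0.20 rather than assuming
control; inference about predictive power rests on the leave-one-out
procedures instead.

Leave-one-out comes in two flavours. The voxel-level fit scores each
patient on the map built from the remaining n−1 and regresses observed
severity on these scores (internal consistency). The patient-level
prediction additionally fits the score→severity regression inside each
training fold and predicts the held-out severity; predictive power is the
squared Pearson correlation between predicted and observed across folds.
A fold whose training map is empty predicts the training-mean severity.
When *every* fold is empty the procedure reports R² = 0 with a warning:
the leave-one-out means are an exact negative linear function of the
held-out value, so the apparent correlation in that degenerate case is
pure mean-leakage, not prediction. Risk strata are predicted-severity
tertiles (ties broken by input order) compared by pairwise Mann–Whitney U
with Benjamini–Hochberg correction over the three contrasts.

## Reprogramming

The search enumerates contact × amplitude (±50% of baseline in 0.5 mA
steps) × pulse width ({40, 60, 90, 120} µs) at fixed frequency (the VTA
model is frequency-blind). A candidate is feasible if its sweet-spot score
keeps at least 95% of baseline (relative tolerance, configurable); among
feasible candidates that *strictly* reduce the sour score, the lowest sour
wins and TEED breaks ties. A sour-free baseline, or one no candidate
improves, is returned unchanged — the objective is this package's own
lexicographic definition, chosen because side-effect reduction subject to
preserved benefit is the clinically stated goal and admits exhaustive
search (the enumeration optimum is also the test oracle).

## Connectomics

A streamline engages a VTA if any point of the polyline, resampled to
≤ 0.5 mm segments, falls in a mask voxel — a cheap criterion that matches
dense 0.05 mm sampling away from the voxelization boundary (tested). Tract
counts are correlated with severity by tie-aware Spearman coefficients,
BH-FDR corrected across tracts. The suite's calibration (28 random-count
tracts, n = 55, 100 replicates) confirms that FDR-significant tracts under
the null are essentially absent — the negative-control regime this analysis
is meant to operate in. Mixed-effects variants are out of scope.

## Cohort statistics

Conventions pinned by tests because they change printed numbers:

* Pearson χ² **without** Yates continuity correction (the corrected value
  on the cohort's 2×2 sex table would be ≈ 5.6, not 6.98);
* odds ratio ad/bc with a Woolf log-CI (Haldane–Anscombe 0.5 on zero
  cells, flagged);
* Spearman ρ with average ranks for ties and the t-approximation p-value;
* Gaussian-identity GLM = OLS with fixed dummy references (male, cervical,
  non-responder), a pairwise |r| > 0.7 collinearity report, and a hard
  error (naming aliased columns) on rank deficiency instead of silent
  dropping;
* paired t **and** exact Wilcoxon signed-rank (zeros dropped, average
  ranks) both reported — small-sample paired claims can differ between
  them, so neither is privileged;
* Benjamini–Hochberg step-up FDR; paired Cohen's d = mean(Δ)/SD(Δ) with
  the n−1 SD, undefined (error) at zero SD.

## Synthetic data

The generator is the study-conditions oracle: every stage of the pipeline
is tested against data whose ground truth is known by construction.

* **Cohort** (n = 60 default): bilateral quadripolar leads, active contacts
  at the nominal right-GPi target (20, −12, −4) mm (left mirrored) plus
  isotropic Gaussian jitter (SD 1.0 mm — the scale of template-space
  electrode localization error); amplitude ~ N(3.4, 1.1) mA, pulse width
  ~ N(112, 43) µs, frequency ~ N(153, 24) Hz, matching the retrospective
  cohort's programming distribution. Severity = 1.5 × (fraction of the
  planted 3 mm "sour" sphere at (22, −10, −6) covered by the pooled VTA)
  + 0.25·[female] + 0.01·(onset − 37) + N(0, 0.4). The covered-share
  overlap fraction is grid-independent and monotone in VTA size, so larger
  pulse widths raise severity by construction — the pulse-width risk
  mechanism. The planted signal carries ≈ 0.5× the noise variance: a
  recoverable but realistically noisy anatomical effect. Dystonia
  improvement derives from overlap with a "sweet" sphere at the target,
  3–4 mm from the sour sphere, keeping benefit and side-effect substrates
  spatially segregated.
* **Landmarks**: a fixed 21-point hand template driven by
  v(t) = A·(1 − decay·⌊f·t⌋)·(0.5 − 0.5·cos 2πft) with per-landmark
  Gaussian jitter; a severity knob maps 0–1 to slower, smaller, more
  decrementing movements.
* **Tracts**: straight bundles whose closest approach to the target is
  exactly the configured clearance (half-normal outward spread), so
  intersection truth is known.

What passing on this generator does **not** show: real electrode
localization error structure, non-spherical activation fields, rater noise
in clinical scores, camera perspective effects, or anatomically realistic
fiber geometry. The synthetic experiments validate the *machinery*
(recovery, calibration, oracle equivalence), not clinical effect sizes.

## Problem sizes and numerics

The default analysis grid spans 24 × 26 × 32 mm at 0.5 mm isotropic
(~165k voxels); the leave-one-out procedures restrict per-fold t-tests to
the full-cohort testable voxel set (a provable superset of every fold's)
for speed. Null calibrations use 100 replicate cohorts. Degenerate inputs
are decided, not left to float behaviour: zero pooled variance with equal
means gives t = 0; constant signals give zero cycles; empty spot maps are
legal (empty cluster tables); both-empty Dice is 0 by convention with a
warning. Seeds are explicit everywhere; all generators are pure functions
of (config, seed).
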