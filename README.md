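# pallidomap

Analysis pipeline for **stimulation-induced bradykinesia in pallidal deep
brain stimulation (DBS) for dystonia**: bespoke bradykinesia scores,
markerless hand-kinematic features, volume-of-tissue-activated (VTA) based
probabilistic "sour spot" mapping with leave-one-out validation and risk
stratification, machine-assisted reprogramming, tract-intersection
statistics, and the accompanying cohort statistics — all exercisable on a
fully synthetic cohort with a planted anatomical effect.

## Who it is for

Movement-disorder researchers analyzing cohorts of GPi-DBS dystonia
patients who develop parkinsonian side effects, and methodologists who want
a tested, self-contained reference implementation of voxelwise
stimulation-outcome mapping with leave-one-out cross-validation.

## The model

**Scores.** Heterogeneous retrospective video ratings are normalized by the
Normalized Bradykinesia Score, the mean of the rated MDS-UPDRS III
bradykinesia subitems (items 3.4–3.8),

    NBS = Σ(subitem scores) / number of subitems used,

and postoperative change is the Bradykinesia Difference Score,

    BDS = NBS_post − NBS_pre,

with BDS > 0 read as worsening (any strictly positive value).

**Mapping.** Each hemisphere's stimulation is modelled as a spherical VTA
at the active contact with radius r(A, pw) = k₁·√A·(pw/60 µs)^k₂ (monotone
in amplitude and pulse width); left-side VTAs are mirrored to the right so
both hemispheres pool on one grid. At every voxel covered by ≥ 5 patients
on each side of the split, a two-sample t-test compares BDS between
stimulated and unstimulated patients (t > 0 = stimulated worse);
26-connected clusters of > 500 voxels at uncorrected p < 0.05 form the sour
spot. A patient's risk score is the mean spot weight inside their VTA, and
predictive power is assessed by patient-level leave-one-out
cross-validation (each patient scored on a map built from all others).

**Kinematics.** Finger-tapping and hand-opening landmark series (21-point
hand schema) yield five features per task — frequency, amplitude, speed,
amplitude decay and velocity decay — from thumb–index distance normalized
to thumb length, or MCP extension angles.

## Worked example

```python
from pallidomap import (SyntheticConfig, generate_cohort, voxelwise_tmap,
                        extract_spot, loo_predict)
from pallidomap.mapping import MappingCohort

cohort = generate_cohort(SyntheticConfig(), seed=1)   # n=60, planted sour sphere
statmap = voxelwise_tmap(cohort.vta_sets, cohort.severity, grid=cohort.grid)
sour = extract_spot(statmap, "sour")
c = sour.cluster_table[0]
print(f"sour cluster: {c['voxel_count']} voxels, centroid "
      f"({c['centroid_mm'][0]:.1f}, {c['centroid_mm'][1]:.1f}, "
      f"{c['centroid_mm'][2]:.1f}) mm, peak |t| = {c['peak_abs_t']:.2f}")

mc = MappingCohort.from_vtas([r.patient_id for r in cohort.records],
                             cohort.vta_sets, cohort.severity, cohort.grid)
pred = loo_predict(mc)
print(f"patient-level LOOCV: R^2 = {pred['r2']:.3f}, p = {pred['p']:.4f}")
```

prints

```
sour cluster: 961 voxels, centroid (22.3, -11.4, -5.8) mm, peak |t| = 5.36
patient-level LOOCV: R^2 = 0.117, p = 0.0073
```

The generator planted its "sour" sphere at (22, −10, −6) mm with a
3 mm radius: the recovered cluster centroid lies within 1.5 mm of it, and
the held-out risk scores significantly predict severity even though the
planted effect carries only about a third of the outcome variance.

A command-line interface mirrors the stages
(`pallidomap {run|simulate|kinematics|stats} ...`); `pallidomap run` writes
a JSON report with the version and configuration hash embedded.

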