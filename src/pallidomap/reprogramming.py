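"""Machine-assisted reprogramming against the sour/sweet spot maps.

For one patient and lead, enumerate a grid of candidate settings (contact x
amplitude x pulse width; frequency held fixed — the VTA model is
frequency-blind) and pick, among candidates whose sweet-spot score keeps at
least (1 - tolerance) of the baseline sweet score, the one with the lowest
sour-spot score; ties are broken by lower total electrical energy (TEED,
computed with an explicit nominal impedance).  The search is exhaustive, so
the returned optimum is the global optimum of this lexicographic objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import VTA, HemisphereSetting, PatientRecord, SpotMap, VolumeGrid
from .scores import teed
from .stats import cohens_d_paired
from .vta import Lead, VTAModel, contact_positions, mirror_to_right, vta_radius, voxelize_vta

__all__ = ["SearchSpace", "ReprogrammingResult", "simulate_reprogramming",
           "cohort_reprogramming_effect"]


@dataclass(frozen=True)
class SearchSpace:
    """Enumerable candidate settings around a baseline.

    Amplitudes span +-``amplitude_span`` (relative) around the baseline in
    ``amplitude_step_ma`` steps; pulse widths come from a fixed clinical
    menu; all contacts of the lead are candidates.
    """

    amplitude_step_ma: float = 0.5
    amplitude_span: float = 0.5
    pulse_widths_us: tuple[float, ...] = (40.0, 60.0, 90.0, 120.0)
    sweet_tolerance: float = 0.05
    impedance_ohm: float = 1000.0  # nominal, for the TEED tie-break only


@dataclass
class ReprogrammingResult:
    patient_id: str
    side: str
    baseline: HemisphereSetting
    best: HemisphereSetting
    baseline_sour: float
    best_sour: float
    baseline_sweet: float
    best_sweet: float
    feasible: bool
    changed: bool


def _setting_scores(
    center: np.ndarray,
    radius: float,
    sweet: SpotMap,
    sour: SpotMap,
    mirror: bool,
    grid: VolumeGrid,
) -> tuple[float, float]:
    c = mirror_to_right(center) if mirror else center
    vta = voxelize_vta(c, radius, grid)
    cov = vta.mask.values.astype(bool)
    n = cov.sum()
    return (
        float(sweet.weight.values[cov].sum() / n),
        float(sour.weight.values[cov].sum() / n),
    )


def simulate_reprogramming(
    record: PatientRecord,
    lead: Lead,
    side: str,
    sweet: SpotMap,
    sour: SpotMap,
    space: SearchSpace = SearchSpace(),
    model: VTAModel = VTAModel(),
) -> ReprogrammingResult:
    """Exhaustive search for settings with less sour exposure at preserved benefit.

    A candidate must keep the sweet score within ``space.sweet_tolerance``
    (relative) of baseline and *strictly* reduce the sour score; among such
    candidates the lowest sour wins, with TEED as the tie-break.  A baseline
    that is already sour-free, or that no feasible candidate improves on, is
    returned unchanged — reprogramming never touches a working program
    without a side-effect rationale.
    """
    if side not in record.hemisphere_settings:
        raise ValueError(f"{record.patient_id}: no settings for side {side}")
    baseline = record.hemisphere_settings[side]
    grid = sour.mask
    mirror = side == "left"
    positions = contact_positions(lead)
    base_center = positions[baseline.active_contact]
    base_radius = vta_radius(baseline.amplitude_ma, baseline.pulse_width_us, model)
    base_sweet, base_sour = _setting_scores(
        base_center, base_radius, sweet, sour, mirror, grid
    )
    sweet_floor = base_sweet - space.sweet_tolerance * abs(base_sweet)

    amp_lo = baseline.amplitude_ma * (1 - space.amplitude_span)
    amp_hi = baseline.amplitude_ma * (1 + space.amplitude_span)
    n_steps = int(np.floor((amp_hi - amp_lo) / space.amplitude_step_ma + 1e-9))
    amplitudes = amp_lo + space.amplitude_step_ma * np.arange(n_steps + 1)
    amplitudes = amplitudes[amplitudes > 0]

    best = baseline
    best_scores = (base_sweet, base_sour)
    feasible_any = base_sweet >= sweet_floor
    # a sour-free baseline is never touched: there is nothing to improve
    if base_sour > 0:
        best_key = None  # (sour, teed) of the best strictly-improving candidate
        for contact in range(lead.n_contacts):
            for amp in amplitudes:
                for pw in space.pulse_widths_us:
                    radius = vta_radius(float(amp), float(pw), model)
                    sw, so = _setting_scores(
                        positions[contact], radius, sweet, sour, mirror, grid
                    )
                    if sw < sweet_floor:
                        continue
                    feasible_any = True
                    if so >= base_sour:
                        continue  # only strict sour reductions beat the baseline
                    key = (so, teed(float(amp), float(pw), baseline.frequency_hz,
                                    space.impedance_ohm))
                    if best_key is None or key < best_key:
                        best_key = key
                        best = HemisphereSetting(
                            active_contact=contact,
                            amplitude_ma=float(amp),
                            pulse_width_us=float(pw),
                            frequency_hz=baseline.frequency_hz,
                        )
                        best_scores = (sw, so)
    return ReprogrammingResult(
        patient_id=record.patient_id,
        side=side,
        baseline=baseline,
        best=best,
        baseline_sour=base_sour,
        best_sour=best_scores[1],
        baseline_sweet=base_sweet,
        best_sweet=best_scores[0],
        feasible=feasible_any,
        changed=best != baseline,
    )


def cohort_reprogramming_effect(
    records: list[PatientRecord],
    leads: dict[str, dict[str, Lead]],
    sweet: SpotMap,
    sour: SpotMap,
    space: SearchSpace = SearchSpace(),
    model: VTAModel = VTAModel(),
) -> dict:
    """Paired before/after effect of per-patient reprogramming.

    Optimizes every implanted hemisphere of every patient, averages the
    sour and sweet scores over hemispheres per patient, and reports the
    paired effect on sour scores: Cohen's d for paired samples
    (mean difference / SD of differences) and the Wilcoxon signed-rank p,
    plus the mean relative sweet-score change.
    """
    if len(records) < 5:
        raise ValueError("cohort reprogramming needs at least 5 patients")
    before, after, sweet_rel = [], [], []
    results = []
    for rec in records:
        sours_b, sours_a, sweets_b, sweets_a = [], [], [], []
        for side in rec.hemisphere_settings:
            res = simulate_reprogramming(
                rec, leads[rec.patient_id][side], side, sweet, sour, space, model
            )
            results.append(res)
            sours_b.append(res.baseline_sour)
            sours_a.append(res.best_sour)
            sweets_b.append(res.baseline_sweet)
            sweets_a.append(res.best_sweet)
        before.append(np.mean(sours_b))
        after.append(np.mean(sours_a))
        b, a = np.sum(sweets_b), np.sum(sweets_a)
        sweet_rel.append((a - b) / abs(b) if b != 0 else 0.0)
    before = np.asarray(before)
    after = np.asarray(after)
    diff = before - after
    if np.all(diff == 0):
        return {"results": results, "cohen_d": 0.0, "wilcoxon_p": 1.0,
                "mean_sour_before": float(before.mean()),
                "mean_sour_after": float(after.mean()),
                "mean_sweet_rel_change": float(np.mean(sweet_rel))}
    try:
        d = cohens_d_paired(before, after)
    except ValueError:
        d = float("inf")  # constant nonzero improvement
        warnings.warn("zero variance of paired differences; effect size unbounded")
    nz = diff[diff != 0]
    mode = "exact" if len(nz) <= 25 else "auto"
    p = float(stats.wilcoxon(nz, mode=mode).pvalue) if len(nz) else 1.0
    return {
        "results": results,
        "cohen_d": float(d),
        "wilcoxon_p": p,
        "mean_sour_before": float(before.mean()),
        "mean_sour_after": float(after.mean()),
        "mean_sweet_rel_change": float(np.mean(sweet_rel)),
    }
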