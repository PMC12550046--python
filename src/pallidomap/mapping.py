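"""Voxelwise probabilistic outcome mapping and risk stratification.

The central construction is a voxelwise two-sample t-test: at every voxel
covered by enough patients' VTAs on each side of the split, severity (the
bradykinesia difference score) is compared between patients whose
stimulation reaches that voxel and patients whose stimulation does not.
The t-statistic is signed so that t > 0 means the stimulated group is
*worse*.  Contiguous clusters (26-connectivity) of more than
``min_cluster_voxels`` voxels at uncorrected p < 0.05 form the "sour spot"
(or, with the opposite sign and a benefit outcome, a "sweet spot").

A patient's risk score is the mean map weight (the t-value inside
significant clusters, zero elsewhere) over their VTA voxels.  Internal
consistency and predictive power are assessed by leave-one-out procedures:

* :func:`loo_fit` — voxel-level fit: each patient is scored on the map
  built from the remaining patients, and observed severity is regressed on
  those scores;
* :func:`loo_predict` — patient-level prediction: the held-out patient's
  severity is predicted from the training-fold regression, and predictive
  power is the squared Pearson correlation between predicted and observed
  severity across folds.

Note the cluster rule (uncorrected voxel p with a size threshold) controls
neither voxel- nor cluster-level family-wise error; the leave-one-out
procedures and the null calibration in the test-suite are the guard against
overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .data_model import (
    VTA,
    GridMismatchError,
    SpotMap,
    StatMap,
    VolumeGrid,
    check_same_grid,
)

__all__ = [
    "MappingConfig",
    "MappingCohort",
    "voxelwise_tmap",
    "extract_spot",
    "score_patient",
    "loo_fit",
    "loo_predict",
    "stratify",
    "dice",
]

#: 26-connectivity structuring element for cluster labelling.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class MappingConfig:
    """Conventions of the voxelwise analysis.

    min_group : minimum patients on each side of the voxel split for the
        voxel to be tested at all.
    p_threshold / min_cluster_voxels : cluster-forming threshold
        (uncorrected) and the strictly-greater-than size rule.
    welch : use Welch's t instead of the pooled-variance t.
    weight_kind : per-voxel weight stored in the spot map — the signed
        t-value ("t", default) or 1 - p ("one_minus_p").
    """

    min_group: int = 5
    p_threshold: float = 0.05
    min_cluster_voxels: int = 500
    welch: bool = False
    weight_kind: str = "t"


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class MappingCohort:
    """Per-patient voxel coverage and severity on a shared grid.

    ``coverage`` is an (n_patients, n_voxels) boolean matrix over the
    flattened grid: True where any of the patient's VTAs covers the voxel.
    """

    grid: VolumeGrid
    patient_ids: list[str]
    severity: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        n = len(self.patient_ids)
        if self.severity.shape != (n,):
            raise ValueError("severity must have one value per patient")
        if not np.all(np.isfinite(self.severity)):
            raise ValueError("severity must be finite")
        nvox = int(np.prod(self.grid.shape))
        if self.coverage.shape != (n, nvox):
            raise ValueError("coverage must be (n_patients, n_voxels)")

    @classmethod
    def from_vtas(
        cls,
        patient_ids: list[str],
        vta_sets: list[list[VTA]],
        severity: np.ndarray,
        grid: VolumeGrid | None = None,
    ) -> "MappingCohort":
        if grid is None:
            grid = vta_sets[0][0].mask
        coverage = np.zeros((len(vta_sets), int(np.prod(grid.shape))), dtype=bool)
        for i, vtas in enumerate(vta_sets):
            for v in vtas:
                check_same_grid(grid, v.mask)
                coverage[i] |= v.mask.values.ravel().astype(bool)
        return cls(grid, list(patient_ids), np.asarray(severity, float), coverage)

    @property
    def n(self) -> int:
        return len(self.patient_ids)


# ---------------------------------------------------------------------------
# voxelwise t-test

def _tmap_arrays(
    coverage: np.ndarray,
    severity: np.ndarray,
    min_group: int,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test over voxels.

    Returns flat arrays (t, p, n_in, tested); t and p are NaN where the
    minimum-group rule fails.  The t is signed stimulated-minus-unstimulated.
    """
    n = len(severity)
    n_in = coverage.sum(axis=0)
    n_out = n - n_in
    tested = (n_in >= min_group) & (n_out >= min_group)
    t = np.full(coverage.shape[1], np.nan)
    p = np.full(coverage.shape[1], np.nan)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return t, p, n_in, tested
    cov = coverage[:, idx]
    s = severity.astype(np.float64)
    n1 = n_in[idx].astype(np.float64)
    n0 = n - n1
    sum1 = s @ cov
    sumsq1 = (s * s) @ cov
    mean1 = sum1 / n1
    mean0 = (s.sum() - sum1) / n0
    ss1 = sumsq1 - n1 * mean1**2
    ss0 = ((s * s).sum() - sumsq1) - n0 * mean0**2
    ss1 = np.maximum(ss1, 0.0)
    ss0 = np.maximum(ss0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            v1 = ss1 / (n1 - 1)
            v0 = ss0 / (n0 - 1)
            se = np.sqrt(v1 / n1 + v0 / n0)
            tv = (mean1 - mean0) / se
            df = (v1 / n1 + v0 / n0) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
            )
        else:
            sp2 = (ss1 + ss0) / (n - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
            tv = (mean1 - mean0) / se
            df = np.full_like(tv, n - 2)
    # zero pooled variance with equal means -> t = 0 (identical severities)
    zero_se = se == 0
    tv = np.where(zero_se & (mean1 == mean0), 0.0, tv)
    pv = 2 * stats.t.sf(np.abs(tv), df)
    pv = np.where(np.isnan(tv), np.nan, pv)
    t[idx] = tv
    p[idx] = pv
    return t, p, n_in, tested


def voxelwise_tmap(
    vta_sets: list[list[VTA]],
    severity: np.ndarray,
    config: MappingConfig = MappingConfig(),
    grid: VolumeGrid | None = None,
) -> StatMap:
    """Voxelwise two-sample t-map of severity, stimulated vs not stimulated.

    A patient "stimulates" a voxel if any of their VTAs covers it.  Voxels
    with fewer than ``config.min_group`` patients in either group are not
    tested (NaN in t/p, 0 in ``tested``).
    """
    severity = np.asarray(severity, dtype=float)
    if not np.all(np.isfinite(severity)):
        raise ValueError("severity must be finite")
    cohort = MappingCohort.from_vtas(
        [f"p{i}" for i in range(len(vta_sets))], vta_sets, severity, grid
    )
    return _tmap_from_cohort(cohort, config)


def _tmap_from_cohort(cohort: MappingCohort, config: MappingConfig) -> StatMap:
    t, p, n_in, tested = _tmap_arrays(
        cohort.coverage, cohort.severity, config.min_group, config.welch
    )
    if not tested.any():
        warnings.warn("no voxel satisfies the minimum-group rule; empty statistical map")
    g = cohort.grid
    shape = g.shape
    return StatMap(
        t=g.like(t.reshape(shape)),
        p=g.like(p.reshape(shape)),
        n_in=g.like(n_in.reshape(shape).astype(float)),
        n_out=g.like((len(cohort.severity) - n_in).reshape(shape).astype(float)),
        tested=g.like(tested.reshape(shape).astype(float)),
    )


# ---------------------------------------------------------------------------
# spot extraction

def extract_spot(
    statmap: StatMap,
    polarity: str = "sour",
    config: MappingConfig = MappingConfig(),
) -> SpotMap:
    """Threshold + cluster a statistical map into a weighted spot mask.

    Voxels with p < ``p_threshold`` and a t-sign matching the polarity
    (sour: t > 0, stimulated worse; sweet: t < 0) are grouped into
    26-connected components; components of strictly more than
    ``min_cluster_voxels`` voxels survive.  The weight inside surviving
    clusters is the per-voxel statistic (|t| by default, signed so sour
    weights are positive), zero elsewhere.
    """
    t = statmap.t.values
    p = statmap.p.values
    with np.errstate(invalid="ignore"):
        if polarity == "sour":
            supra = (p < config.p_threshold) & (t > 0)
        elif polarity == "sweet":
            supra = (p < config.p_threshold) & (t < 0)
        else:
            raise ValueError(f"invalid polarity {polarity!r}")
    labels, n_labels = ndimage.label(supra, structure=_CONN26)
    mask = np.zeros_like(supra, dtype=bool)
    table: list[dict] = []
    if n_labels:
        counts = np.bincount(labels.ravel())[1:]  # skip background
        keep = np.flatnonzero(counts > config.min_cluster_voxels) + 1
        for cid in keep:
            sel = labels == cid
            mask |= sel
            ijk = np.argwhere(sel)
            centroid = statmap.t.voxel_to_world(ijk).mean(axis=0)
            table.append(
                {
                    "cluster_id": int(cid),
                    "voxel_count": int(sel.sum()),
                    "centroid_mm": centroid.tolist(),
                    "peak_abs_t": float(np.nanmax(np.abs(t[sel]))),
                }
            )
    if config.weight_kind == "t":
        weight = np.where(mask, np.abs(t), 0.0)
    elif config.weight_kind == "one_minus_p":
        weight = np.where(mask, 1.0 - p, 0.0)
    else:
        raise ValueError(f"invalid weight_kind {config.weight_kind!r}")
    weight = np.nan_to_num(weight, nan=0.0)
    return SpotMap(
        mask=statmap.t.like(mask.astype(float)),
        weight=statmap.t.like(weight),
        polarity=polarity,
        cluster_table=table,
    )


# ---------------------------------------------------------------------------
# patient scoring

def score_patient(spot: SpotMap, patient_vtas: list[VTA]) -> float:
    """Mean spot weight over the voxels of the patient's (union) VTA.

    Zero when the VTA misses the spot entirely.
    """
    if not patient_vtas:
        raise ValueError("patient has no VTAs")
    union = np.zeros(spot.mask.shape, dtype=bool)
    for v in patient_vtas:
        check_same_grid(spot.mask, v.mask)
        union |= v.mask.values.astype(bool)
    n = union.sum()
    if n == 0:
        raise ValueError("patient VTA is empty")
    return float(spot.weight.values[union].sum() / n)


def _score_from_coverage(weight_flat: np.ndarray, cov_row: np.ndarray) -> float:
    n = cov_row.sum()
    if n == 0:
        raise ValueError("patient VTA is empty")
    return float(weight_flat[cov_row].sum() / n)


def _spot_weight_flat(
    coverage: np.ndarray,
    severity: np.ndarray,
    shape: tuple[int, int, int],
    config: MappingConfig,
    cand_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Fast path: sour-spot weight vector from a coverage matrix.

    ``cand_idx`` restricts computation to a candidate voxel subset of the
    flattened grid (``coverage`` then has one column per candidate); the
    returned weight vector is always over the full grid.
    """
    t, p, _, _ = _tmap_arrays(coverage, severity, config.min_group, config.welch)
    nvox = int(np.prod(shape))
    if cand_idx is not None:
        t_full = np.full(nvox, np.nan)
        p_full = np.full(nvox, np.nan)
        t_full[cand_idx] = t
        p_full[cand_idx] = p
        t, p = t_full, p_full
    with np.errstate(invalid="ignore"):
        supra = (np.nan_to_num(p, nan=1.0) < config.p_threshold) & (
            np.nan_to_num(t, nan=0.0) > 0
        )
    labels, n_labels = ndimage.label(supra.reshape(shape), structure=_CONN26)
    weight = np.zeros(nvox)
    if n_labels:
        counts = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(counts > config.min_cluster_voxels) + 1
        if keep.size:
            mask = np.isin(labels, keep).ravel()
            if config.weight_kind == "t":
                weight[mask] = np.abs(t[mask])
            else:
                weight[mask] = 1.0 - p[mask]
    return weight


def _loo_candidates(cohort: MappingCohort, config: MappingConfig) -> np.ndarray:
    """Voxels that could satisfy the group rule in any leave-one-out fold.

    Dropping a patient can only shrink per-voxel group sizes, so the full
    cohort's tested set is a superset of every fold's tested set.
    """
    n_in = cohort.coverage.sum(axis=0)
    n_out = cohort.n - n_in
    return np.flatnonzero((n_in >= config.min_group) & (n_out >= config.min_group))


# ---------------------------------------------------------------------------
# leave-one-out procedures

def loo_fit(cohort: MappingCohort, config: MappingConfig = MappingConfig()) -> dict:
    """Voxel-level leave-one-out fit.

    Each patient is scored on the sour spot built from the other n-1
    patients; observed severity is regressed on these scores (OLS).
    Returns {"scores", "r2", "p", "slope", "intercept"}.
    """
    n = cohort.n
    if n < 10:
        raise ValueError(f"leave-one-out analysis needs n >= 10, got {n}")
    cand = _loo_candidates(cohort, config)
    cov_cand = cohort.coverage[:, cand]
    scores = np.empty(n)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        weight = _spot_weight_flat(
            cov_cand[rest], cohort.severity[rest], cohort.grid.shape, config, cand
        )
        scores[i] = _score_from_coverage(weight, cohort.coverage[i])
    if np.ptp(scores) == 0:
        warnings.warn("degenerate leave-one-out scores (all equal); R^2 = 0")
        return {"scores": scores, "r2": 0.0, "p": 1.0, "slope": 0.0,
                "intercept": float(cohort.severity.mean())}
    fit = stats.linregress(scores, cohort.severity)
    return {
        "scores": scores,
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def loo_predict(cohort: MappingCohort, config: MappingConfig = MappingConfig()) -> dict:
    """Patient-level leave-one-out prediction.

    For each held-out patient the sour spot and the score->severity
    regression are built on the training fold only; the held-out severity is
    then predicted from the held-out patient's score on the training map.
    Folds whose training map is empty (or has degenerate scores) predict the
    training-mean severity.  Returns {"predicted", "observed", "r2", "p"}
    where R^2 is the squared Pearson correlation between predicted and
    observed severity across folds.
    """
    n = cohort.n
    if n < 10:
        raise ValueError(f"leave-one-out analysis needs n >= 10, got {n}")
    cand = _loo_candidates(cohort, config)
    cov_cand = cohort.coverage[:, cand]
    predicted = np.empty(n)
    informative = np.zeros(n, dtype=bool)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        cov_tr = cohort.coverage[rest]
        sev_tr = cohort.severity[rest]
        weight = _spot_weight_flat(
            cov_cand[rest], sev_tr, cohort.grid.shape, config, cand
        )
        if not weight.any():
            predicted[i] = sev_tr.mean()
            continue
        tr_scores = cov_tr @ weight / cov_tr.sum(axis=1)
        if np.ptp(tr_scores) == 0:
            predicted[i] = sev_tr.mean()
            continue
        fit = stats.linregress(tr_scores, sev_tr)
        score_i = _score_from_coverage(weight, cohort.coverage[i])
        predicted[i] = fit.intercept + fit.slope * score_i
        informative[i] = True
    observed = cohort.severity
    out = {
        "predicted": predicted,
        "observed": observed,
        "n_informative_folds": int(informative.sum()),
    }
    if not informative.any():
        # every fold fell back to the training-mean: the apparent (perfectly
        # negative) correlation is pure leave-one-out mean leakage, not a
        # map-based prediction
        warnings.warn(
            "no fold produced a spot map; leave-one-out prediction is undefined"
        )
        out.update(r2=0.0, p=1.0, r=0.0)
        return out
    if np.ptp(predicted) == 0:
        warnings.warn("constant leave-one-out predictions; no predictive power")
        out.update(r2=0.0, p=1.0, r=0.0)
        return out
    r, p = stats.pearsonr(predicted, observed)
    out.update(r2=float(r**2), p=float(p), r=float(r))
    return out


# ---------------------------------------------------------------------------
# risk stratification

def stratify(
    predicted: np.ndarray,
    observed: np.ndarray,
    patient_ids: list[str] | None = None,
) -> dict:
    """Tertile risk strata on predicted severity, with pairwise tests.

    Patients are sorted by predicted severity (ties broken by input order,
    i.e. patient id order) and split into low/medium/high tertiles; observed
    severity is compared between strata with pairwise two-sided
    Mann-Whitney U tests, BH-FDR corrected over the three comparisons.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(predicted)
    if n < 3:
        raise ValueError("need at least 3 patients to stratify")
    if len(np.unique(predicted)) < 3:
        warnings.warn("fewer than 3 distinct predictions; strata will share values")
    order = np.argsort(predicted, kind="stable")
    groups = np.array_split(order, 3)
    labels = np.empty(n, dtype=object)
    for name, idx in zip(("low", "medium", "high"), groups):
        labels[idx] = name
    pairs = [("low", "medium"), ("low", "high"), ("medium", "high")]
    pvals = []
    stats_u = []
    for a, b in pairs:
        xa = observed[labels == a]
        xb = observed[labels == b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = np.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        pvals.append(float(p))
        stats_u.append(float(u) if np.isfinite(u) else None)
    from .stats import fdr_adjust

    p_fdr = fdr_adjust(np.asarray(pvals))
    comparisons = [
        {"pair": f"{a}_vs_{b}", "u": u, "p": p, "p_fdr": q}
        for (a, b), u, p, q in zip(pairs, stats_u, pvals, p_fdr)
    ]
    return {
        "labels": labels,
        "strata_sizes": {k: int((labels == k).sum()) for k in ("low", "medium", "high")},
        "comparisons": comparisons,
    }


# ---------------------------------------------------------------------------
# map overlap

def dice(mask_a: VolumeGrid, mask_b: VolumeGrid) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two binary masks."""
    check_same_grid(mask_a, mask_b)
    a = mask_a.values.astype(bool)
    b = mask_b.values.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 0 by convention")
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
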