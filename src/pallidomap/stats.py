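"""Cohort statistics with pinned conventions.

Thin wrappers over scipy/statsmodels that fix the exact conventions the
analysis depends on: Pearson chi-square *without* continuity correction,
Woolf (log) confidence intervals for the odds ratio, average-rank Spearman
with the t-approximation p-value, Gaussian-identity GLM (= OLS) with a
collinearity screen, paired t plus exact Wilcoxon signed-rank (zeros
dropped), Benjamini-Hochberg FDR, and the paired-samples Cohen's d
(mean difference over the SD of the differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_chi2",
    "odds_ratio",
    "spearman",
    "fit_glm",
    "GLMResult",
    "paired_compare",
    "fdr_adjust",
    "cohens_d_paired",
]


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("table total must be > 0")
    return t


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction), two-sided p."""
    t = _as_2x2(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be > 0")
    return float(chi2), float(p)


def odds_ratio(table) -> tuple[float, tuple[float, float]]:
    """Odds ratio ad/bc with the Woolf 95% CI.

    A zero cell triggers the Haldane-Anscombe 0.5 correction (with a
    warning) so the ratio stays finite.
    """
    t = _as_2x2(table)
    if np.any(t == 0):
        warnings.warn("zero cell: applying Haldane-Anscombe 0.5 correction")
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return float(or_), (float(lo), float(hi))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; p via the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GLMResult:
    params: pd.Series
    pvalues: pd.Series
    adj_r2: float
    r2: float
    n: int
    collinear_pairs: list[tuple[str, str, float]]


_CATEGORICAL_REFERENCE = {
    "sex": "male",
    "dystonia_type": "cervical",
    "responder_category": "non",
}


def fit_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    collinearity_threshold: float = 0.7,
) -> GLMResult:
    """Gaussian-identity GLM (ordinary least squares) of severity on predictors.

    Categorical predictors (sex, dystonia type, responder category) are
    dummy-coded against fixed references (male / cervical / non-responder).
    Pairs of numeric predictors with |r| above ``collinearity_threshold``
    are reported in the result; a rank-deficient design raises an error
    naming the aliased columns rather than silently dropping them.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    cols = []
    for name in X.columns:
        col = X[name]
        if name in _CATEGORICAL_REFERENCE or col.dtype == object:
            ref = _CATEGORICAL_REFERENCE.get(name)
            dummies = pd.get_dummies(col, prefix=name, dtype=float)
            refcol = f"{name}_{ref}" if ref is not None else dummies.columns[0]
            if refcol in dummies.columns:
                dummies = dummies.drop(columns=[refcol])
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame())
    design = pd.concat(cols, axis=1)
    numeric_names = [c for c in X.columns if c not in _CATEGORICAL_REFERENCE
                     and X[c].dtype != object]
    collinear = []
    for i, a in enumerate(numeric_names):
        for b in numeric_names[i + 1:]:
            if np.ptp(X[a]) == 0 or np.ptp(X[b]) == 0:
                continue
            r = np.corrcoef(X[a].astype(float), X[b].astype(float))[0, 1]
            if abs(r) > collinearity_threshold:
                collinear.append((a, b, float(r)))
    design_c = sm.add_constant(design, has_constant="add")
    if len(y) <= design_c.shape[1]:
        raise ValueError(
            f"n={len(y)} must exceed the number of parameters ({design_c.shape[1]})"
        )
    rank = np.linalg.matrix_rank(design_c.to_numpy())
    if rank < design_c.shape[1]:
        # identify aliased columns by incremental rank
        aliased, kept = [], []
        for c in design_c.columns:
            trial = design_c[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    model = sm.OLS(y, design_c).fit()
    return GLMResult(
        params=model.params,
        pvalues=model.pvalues,
        adj_r2=float(model.rsquared_adj),
        r2=float(model.rsquared),
        n=len(y),
        collinear_pairs=collinear,
    )


def paired_compare(a, b) -> dict:
    """Paired comparison: means, two-sided paired t and exact Wilcoxon.

    The Wilcoxon signed-rank test drops zero differences and uses average
    ranks (exact null distribution when feasible).  All-zero differences
    give p = 1 for both tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("paired comparison needs equal-length vectors, n >= 3")
    diff = a - b
    if np.all(diff == 0):
        return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "t_p": 1.0, "wilcoxon_p": 1.0, "n": len(a)}
    t_res = sps.ttest_rel(a, b)
    nz = diff[diff != 0]
    mode = "exact" if len(nz) <= 25 else "auto"
    w_res = sps.wilcoxon(a, b, zero_method="wilcox", mode=mode)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t_stat": float(t_res.statistic),
        "t_p": float(t_res.pvalue),
        "wilcoxon_stat": float(w_res.statistic),
        "wilcoxon_p": float(w_res.pvalue),
        "n": len(a),
    }


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d_paired(a, b) -> float:
    """Paired-samples Cohen's d: mean(a - b) / SD(a - b) with n-1 SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired effect size needs equal-length vectors, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD of differences; paired d undefined")
    return float(diff.mean() / sd)
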