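"""VTA-streamline intersections and tract-wise severity correlations.

Fiber engagement is estimated per tract as the number (and fraction) of
streamlines with at least one point inside the VTA mask, after resampling
each polyline to a maximum segment length so that chords crossing the mask
between sparse vertices are not missed.  Tract counts are then correlated
with bradykinesia severity via tie-aware Spearman coefficients, BH-FDR
corrected across tracts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import VTA, TractSet
from .stats import fdr_adjust, spearman

__all__ = ["resample_polyline", "intersect_streamlines", "tract_correlations"]


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline so no segment exceeds ``step_mm`` (vertices kept)."""
    pts = np.asarray(points, dtype=float)
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step_mm)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def _points_in_mask(vta: VTA, pts: np.ndarray) -> np.ndarray:
    vox = np.round(vta.mask.world_to_voxel(pts)).astype(int)
    shape = np.asarray(vta.mask.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    hit = np.zeros(len(pts), dtype=bool)
    if inside.any():
        v = vox[inside]
        hit[inside] = vta.mask.values[v[:, 0], v[:, 1], v[:, 2]] > 0
    return hit


def intersect_streamlines(
    vta: VTA, tract: list[np.ndarray], step_mm: float = 0.5
) -> tuple[int, float]:
    """Count streamlines of one tract engaged by a VTA.

    A streamline intersects if any point of its polyline, after resampling
    to at most ``step_mm`` per segment, lands in a mask voxel.  Returns
    (intersecting count, fraction of the tract).
    """
    if len(tract) == 0:
        warnings.warn("empty tract; intersection is (0, 0)")
        return 0, 0.0
    count = 0
    for sl in tract:
        pts = resample_polyline(sl, step_mm)
        if _points_in_mask(vta, pts).any():
            count += 1
    return count, count / len(tract)


def tract_correlations(
    counts: pd.DataFrame, severity: np.ndarray
) -> pd.DataFrame:
    """Spearman correlation of per-tract intersection counts with severity.

    ``counts`` is patients x tracts.  Tracts with constant counts get NaN
    rho (no correlation is defined there) and are excluded from the FDR
    correction.  Returns a DataFrame indexed by tract with columns
    rho, p, p_fdr, n.
    """
    severity = np.asarray(severity, dtype=float)
    if len(counts) < 5:
        raise ValueError("tract correlations need at least 5 patients")
    if len(severity) != len(counts):
        raise ValueError("severity length must match the counts rows")
    rows = []
    for tract in counts.columns:
        x = counts[tract].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"tract": tract, "rho": np.nan, "p": np.nan, "n": len(x)})
        else:
            rho, p = spearman(x, severity)
            rows.append({"tract": tract, "rho": rho, "p": p, "n": len(x)})
    df = pd.DataFrame(rows).set_index("tract")
    df["p_fdr"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "p_fdr"] = fdr_adjust(df.loc[ok, "p"].to_numpy())
    return df
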