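"""Core domain types, coordinate conventions and file I/O.

Conventions used throughout the package:

* World coordinates are MNI millimetres in RAS orientation (left hemisphere
  has negative x).  Voxel indices are 0-based and the affine maps the voxel
  index ``(i, j, k)`` to the *centre* of that voxel in mm.
* Any two volumes combined in one computation must share shape and affine;
  a mismatch raises :class:`GridMismatchError` — there is no silent
  resampling anywhere in the pipeline.

Exchange formats are deliberately tool-agnostic: CSV for cohort tables,
NIfTI-1 for volumes, JSON for hand landmarks and results, JSON/TSV polylines
for streamline bundles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RowError",
    "GridMismatchError",
    "QualityError",
    "SubitemRating",
    "HemisphereSetting",
    "PatientRecord",
    "VolumeGrid",
    "VTA",
    "StatMap",
    "SpotMap",
    "TractSet",
    "LandmarkSeries",
    "make_grid",
    "check_same_grid",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_tracts",
    "write_tracts",
]


# ---------------------------------------------------------------------------
# errors

class SchemaError(ValueError):
    """A table or file is missing mandatory structure (e.g. a column)."""


class RowError(ValueError):
    """A single row of a table could not be parsed."""


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class QualityError(ValueError):
    """Input data fails a quality gate (e.g. too many missing frames)."""


# ---------------------------------------------------------------------------
# clinical record types

#: Allowed subitem scores: 0..4 in half-point steps.  Half points are
#: accepted because summed item scores in real rating tables carry them.
_VALID_SCORES = {i / 2 for i in range(9)}

_SEX_SYNONYMS = {
    "f": "female", "female": "female", "w": "female",
    "m": "male", "male": "male",
}
_DYSTONIA_SYNONYMS = {
    "cer": "cervical", "cervical": "cervical",
    "seg": "segmental", "segmental": "segmental",
    "gen": "generalized", "generalized": "generalized", "generalised": "generalized",
}
RESPONDER_CATEGORIES = ("non", "average", "good", "super")


@dataclass(frozen=True)
class SubitemRating:
    """One rated bradykinesia subitem (e.g. MDS-UPDRS III item 3.4)."""

    item_id: str
    score: float
    side: str = "na"  # left / right / axial / na

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValueError("item_id must be non-empty")
        if self.score not in _VALID_SCORES:
            raise ValueError(
                f"subitem score must be in 0..4 in half-point steps, got {self.score}"
            )
        if self.side not in ("left", "right", "axial", "na"):
            raise ValueError(f"invalid side {self.side!r}")


@dataclass(frozen=True)
class HemisphereSetting:
    """Per-hemisphere stimulation programming."""

    active_contact: int
    amplitude_ma: float
    pulse_width_us: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.amplitude_ma < 0:
            raise ValueError("amplitude must be >= 0")
        if self.pulse_width_us <= 0 or self.frequency_hz <= 0:
            raise ValueError("pulse width and frequency must be > 0")


@dataclass
class PatientRecord:
    """One row of a cohort: demographics, programming and derived scores.

    ``nbs_pre``/``nbs_post``/``bds`` stay ``None`` until computed by the
    scores module.  Stimulation parameters are the hemisphere means (the
    per-side settings, when known, live in ``hemisphere_settings``).
    """

    patient_id: str
    sex: str | None = None
    dystonia_type: str | None = None
    age_onset: float | None = None
    age_surgery: float | None = None
    disease_duration: float | None = None
    amplitude_ma: float | None = None
    pulse_width_us: float | None = None
    frequency_hz: float | None = None
    subitems_pre: list[SubitemRating] = field(default_factory=list)
    subitems_post: list[SubitemRating] = field(default_factory=list)
    nbs_pre: float | None = None
    nbs_post: float | None = None
    bds: float | None = None
    dystonia_improvement: float | None = None
    responder_category: str | None = None
    hemisphere_settings: dict[str, HemisphereSetting] = field(default_factory=dict)
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.dystonia_type is not None and self.dystonia_type not in (
            "cervical", "segmental", "generalized"
        ):
            raise ValueError(f"invalid dystonia_type {self.dystonia_type!r}")
        if (
            self.age_onset is not None
            and self.age_surgery is not None
            and self.age_onset > self.age_surgery
        ):
            raise ValueError("age_onset must not exceed age_surgery")
        if self.amplitude_ma is not None and self.amplitude_ma < 0:
            raise ValueError("amplitude must be >= 0")
        if self.responder_category is not None and (
            self.responder_category not in RESPONDER_CATEGORIES
        ):
            raise ValueError(f"invalid responder_category {self.responder_category!r}")
        if self.nbs_pre is not None and self.nbs_post is not None:
            expected = self.nbs_post - self.nbs_pre
            if self.bds is None:
                self.bds = expected
            elif abs(self.bds - expected) > 1e-9:
                raise ValueError("bds inconsistent with nbs_post - nbs_pre")


# ---------------------------------------------------------------------------
# volumetric types

@dataclass
class VolumeGrid:
    """A 3D scalar volume with a voxel-index -> mm world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm, per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different values."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise GridMismatchError("value array shape does not match grid")
        return VolumeGrid(values, self.affine.copy())

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def make_grid(
    origin_mm: Sequence[float],
    shape: Sequence[int],
    spacing_mm: float = 0.5,
    fill: float = 0.0,
) -> VolumeGrid:
    """Build an axis-aligned grid whose voxel (0,0,0) centre sits at ``origin_mm``."""
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("grid shape must be positive")
    affine = np.eye(4)
    affine[:3, :3] *= spacing_mm
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    return VolumeGrid(np.full(shape, fill, dtype=float), affine)


def check_same_grid(*grids: VolumeGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise GridMismatchError(
                "volumes do not share shape/affine; resample explicitly before combining"
            )


@dataclass
class VTA:
    """A binary volume of tissue activated for one lead."""

    patient_id: str
    side: str  # left / right
    center: np.ndarray  # mm, world
    radius: float  # mm
    mask: VolumeGrid
    source_settings: HemisphereSetting | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        self.center = np.asarray(self.center, dtype=float)
        vals = np.unique(self.mask.values)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("VTA mask must be binary")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.values.sum())


@dataclass
class StatMap:
    """Voxelwise two-sample t-test results.

    ``t``/``p`` hold NaN where the minimum-group-size rule was not met
    (``tested`` = 0 there).
    """

    t: VolumeGrid
    p: VolumeGrid
    n_in: VolumeGrid
    n_out: VolumeGrid
    tested: VolumeGrid

    def __post_init__(self) -> None:
        check_same_grid(self.t, self.p, self.n_in, self.n_out, self.tested)
        tested = self.tested.values.astype(bool)
        pvals = self.p.values[tested]
        if pvals.size and (np.nanmin(pvals) < 0 or np.nanmax(pvals) > 1):
            raise ValueError("p values outside [0,1] at tested voxels")


@dataclass
class SpotMap:
    """Thresholded, cluster-filtered outcome map ('sour' or 'sweet' spot)."""

    mask: VolumeGrid
    weight: VolumeGrid
    polarity: str  # sour / sweet
    cluster_table: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.polarity not in ("sour", "sweet"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        check_same_grid(self.mask, self.weight)
        m = self.mask.values.astype(bool)
        if np.any(self.weight.values[~m] != 0):
            raise ValueError("weight must be zero outside the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.values.sum())


# ---------------------------------------------------------------------------
# streamlines

class TractSet(dict):
    """Mapping of tract name -> list of streamlines (each an (N,3) mm array)."""

    def total_streamlines(self) -> int:
        return sum(len(v) for v in self.values())


def _clean_streamline(points: np.ndarray) -> np.ndarray | None:
    """Collapse duplicate consecutive points; drop degenerate (<2 pt) lines."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("streamline must be an (N,3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline coordinates must be finite")
    if len(pts) >= 2:
        keep = np.r_[True, np.any(np.diff(pts, axis=0) != 0, axis=1)]
        pts = pts[keep]
    return pts if len(pts) >= 2 else None


# ---------------------------------------------------------------------------
# hand landmarks

#: Landmark indices of the 21-point hand schema used throughout.
WRIST = 0
THUMB_CHAIN = (1, 2, 3, 4)  # CMC, MCP, IP, tip
THUMB_TIP = 4
INDEX_TIP = 8
FINGER_MCP = {"index": 5, "middle": 9, "ring": 13, "little": 17}
FINGER_TIP = {"index": 8, "middle": 12, "ring": 16, "little": 20}
MIDDLE_MCP = 9
N_LANDMARKS = 21


@dataclass
class LandmarkSeries:
    """Per-frame 2D hand landmarks for one motor task."""

    fps: float
    frames: np.ndarray  # (T, 21, 2) image units
    task: str  # finger_tap / hand_open
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (N_LANDMARKS, 2):
            raise ValueError("frames must have shape (T, 21, 2)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.task not in ("finger_tap", "hand_open"):
            raise ValueError(f"invalid task {self.task!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


# ---------------------------------------------------------------------------
# cohort CSV I/O

_MANDATORY_COLUMNS = ("patient_id", "sex")
_NUMERIC_COLUMNS = {
    "age_onset", "age_surgery", "disease_duration",
    "amplitude_ma", "pulse_width_us", "frequency_hz",
    "nbs_pre", "nbs_post", "bds", "dystonia_improvement",
}


def _parse_float(value, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise RowError(f"row {row}: cannot parse {column}={value!r} as number") from exc


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort table.

    Canonical header: ``patient_id,sex,dystonia_type,age_onset,age_surgery,
    disease_duration,amplitude_ma,pulse_width_us,frequency_hz,...``.
    Unknown columns are kept in ``record.extra`` when numeric, otherwise
    ignored.  Sex and dystonia-type synonyms ("F", "CER", ...) are normalized.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort file") from exc
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    records: list[PatientRecord] = []
    known = {"patient_id", "sex", "dystonia_type", "responder_category"} | _NUMERIC_COLUMNS
    for i, row in df.iterrows():
        sex_raw = row.get("sex")
        sex = None
        if isinstance(sex_raw, str) and sex_raw.strip():
            try:
                sex = _SEX_SYNONYMS[sex_raw.strip().lower()]
            except KeyError as exc:
                raise RowError(f"row {i}: unknown sex {sex_raw!r}") from exc
        dt_raw = row.get("dystonia_type")
        dtype = None
        if isinstance(dt_raw, str) and dt_raw.strip():
            try:
                dtype = _DYSTONIA_SYNONYMS[dt_raw.strip().lower()]
            except KeyError as exc:
                raise RowError(f"row {i}: unknown dystonia_type {dt_raw!r}") from exc
        numeric = {c: _parse_float(row.get(c), c, i) for c in _NUMERIC_COLUMNS if c in df.columns}
        extra = {}
        for c in df.columns:
            if c in known:
                continue
            try:
                v = _parse_float(row.get(c), c, i)
            except RowError:
                continue
            if v is not None:
                extra[c] = v
        rc = row.get("responder_category")
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sex=sex,
                dystonia_type=dtype,
                responder_category=rc if isinstance(rc, str) and rc.strip() else None,
                age_onset=numeric.get("age_onset"),
                age_surgery=numeric.get("age_surgery"),
                disease_duration=numeric.get("disease_duration"),
                amplitude_ma=numeric.get("amplitude_ma"),
                pulse_width_us=numeric.get("pulse_width_us"),
                frequency_hz=numeric.get("frequency_hz"),
                nbs_pre=numeric.get("nbs_pre"),
                nbs_post=numeric.get("nbs_post"),
                bds=numeric.get("bds"),
                dystonia_improvement=numeric.get("dystonia_improvement"),
                extra=extra,
            )
        )
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "dystonia_type": r.dystonia_type,
            "age_onset": r.age_onset,
            "age_surgery": r.age_surgery,
            "disease_duration": r.disease_duration,
            "amplitude_ma": r.amplitude_ma,
            "pulse_width_us": r.pulse_width_us,
            "frequency_hz": r.frequency_hz,
            "nbs_pre": r.nbs_pre,
            "nbs_post": r.nbs_post,
            "bds": r.bds,
            "dystonia_improvement": r.dystonia_improvement,
            "responder_category": r.responder_category,
        }
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    return VolumeGrid(np.asarray(data, dtype=float), np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    values = grid.values
    if np.array_equal(values, values.astype(np.int16)):
        values = values.astype(np.int16)  # lossless for masks and counts
    img = nib.Nifti1Image(values, grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# landmark I/O

def read_landmarks(path, max_missing_fraction: float = 0.2) -> LandmarkSeries:
    """Read a landmark series from JSON or long-format CSV.

    JSON schema: ``{"fps": .., "task": .., "handedness": ..,
    "frames": [[[x, y] * 21], ...]}`` where a frame or a landmark may be
    ``null``.  CSV schema: columns ``frame, landmark_id, x, y`` with fps/task
    carried in ``# fps=..`` / ``# task=..`` header comment lines.

    Frames with missing landmarks are linearly interpolated from the nearest
    complete neighbours; missing frames at either end are dropped.  More than
    ``max_missing_fraction`` missing frames is a :class:`QualityError`.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        if "fps" not in payload or payload["fps"] is None:
            raise SchemaError(f"{path}: fps missing from landmark file")
        fps = float(payload["fps"])
        task = payload.get("task", "finger_tap")
        handedness = payload.get("handedness", "right")
        raw = payload["frames"]
        frames = np.full((len(raw), N_LANDMARKS, 2), np.nan)
        for t, fr in enumerate(raw):
            if fr is None:
                continue
            for l, pt in enumerate(fr):
                if pt is not None:
                    frames[t, l] = pt
    else:
        fps = task = handedness = None
        with open(path) as fh:
            header_meta = {}
            lines = fh.readlines()
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                header_meta[k.strip()] = v.strip()
            else:
                data_lines.append(line)
        if "fps" not in header_meta:
            raise SchemaError(f"{path}: fps missing from landmark file")
        fps = float(header_meta["fps"])
        task = header_meta.get("task", "finger_tap")
        handedness = header_meta.get("handedness", "right")
        from io import StringIO

        df = pd.read_csv(StringIO("".join(data_lines)))
        for col in ("frame", "landmark_id", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
        n_frames = int(df["frame"].max()) + 1
        frames = np.full((n_frames, N_LANDMARKS, 2), np.nan)
        frames[df["frame"].astype(int), df["landmark_id"].astype(int), 0] = df["x"]
        frames[df["frame"].astype(int), df["landmark_id"].astype(int), 1] = df["y"]

    incomplete = np.any(np.isnan(frames), axis=(1, 2))
    if incomplete.mean() > max_missing_fraction:
        raise QualityError(
            f"{path}: {incomplete.mean():.0%} of frames have missing landmarks"
        )
    complete_idx = np.flatnonzero(~incomplete)
    if complete_idx.size < 2:
        raise QualityError(f"{path}: fewer than 2 complete frames")
    # drop leading/trailing incomplete frames, interpolate interior ones
    frames = frames[complete_idx[0] : complete_idx[-1] + 1]
    incomplete = np.any(np.isnan(frames), axis=(1, 2))
    if incomplete.any():
        good = np.flatnonzero(~incomplete)
        t_all = np.arange(frames.shape[0])
        for l in range(N_LANDMARKS):
            for c in range(2):
                col = frames[:, l, c]
                bad = np.isnan(col)
                col[bad] = np.interp(t_all[bad], t_all[~bad], col[~bad])
    return LandmarkSeries(fps=fps, frames=frames, task=task, handedness=handedness)


def write_landmarks(series: LandmarkSeries, path) -> None:
    payload = {
        "fps": series.fps,
        "task": series.task,
        "handedness": series.handedness,
        "frames": series.frames.tolist(),
    }
    with open(str(path), "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# tract I/O

def read_tracts(path) -> TractSet:
    """Read polyline bundles from the canonical JSON dialect or long TSV.

    JSON: ``{"tract_name": [[[x,y,z], ...], ...], ...}``.
    TSV columns: ``tract, streamline, point, x, y, z``.
    Streamlines with fewer than 2 distinct points are dropped with a warning.
    """
    path = str(path)
    dropped = 0
    out = TractSet()
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        for name, lines in payload.items():
            cleaned = []
            for line in lines:
                sl = _clean_streamline(np.asarray(line, dtype=float))
                if sl is None:
                    dropped += 1
                else:
                    cleaned.append(sl)
            out[name] = cleaned
    else:
        df = pd.read_csv(path, sep="\t")
        for col in ("tract", "streamline", "point", "x", "y", "z"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
        for name, tdf in df.groupby("tract", sort=False):
            cleaned = []
            for _, sdf in tdf.groupby("streamline", sort=False):
                sdf = sdf.sort_values("point")
                sl = _clean_streamline(sdf[["x", "y", "z"]].to_numpy(dtype=float))
                if sl is None:
                    dropped += 1
                else:
                    cleaned.append(sl)
            out[name] = cleaned
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} streamline(s) with <2 distinct points")
    return out


def write_tracts(tracts: Mapping[str, list[np.ndarray]], path) -> None:
    payload = {
        name: [np.asarray(sl, dtype=float).tolist() for sl in lines]
        for name, lines in tracts.items()
    }
    with open(str(path), "w") as fh:
        json.dump(payload, fh)
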