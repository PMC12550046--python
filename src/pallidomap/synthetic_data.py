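"""Synthetic cohorts, landmark series and fiber bundles.

Every downstream stage of the pipeline can be exercised without any
external data:

* :func:`table1_fixture` returns the printed per-patient table of the
  prospective cohort (demographics, pre/half-stimulation rating sums and
  programming parameters) as records plus a companion CSV;
* :func:`generate_cohort` emulates a retrospective cohort of bilateral
  pallidal electrodes whose VTA overlap with a planted posterolateral
  "sour" sphere drives a continuous severity outcome (plus sex and
  age-of-onset covariate effects and Gaussian noise) — severity is driven
  by the fraction of the sour sphere covered by the pooled VTA — an
  overlap fraction that is independent of the voxel grid and grows
  monotonically with VTA size, carrying the pulse-width risk mechanism;
* :func:`generate_landmarks` builds kinematically plausible 21-point hand
  series with controllable frequency, amplitude, per-cycle decay and
  landmark jitter;
* :func:`generate_tracts` builds straight streamline bundles passing at a
  configurable clearance from the stimulation target.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    N_LANDMARKS,
    HemisphereSetting,
    LandmarkSeries,
    PatientRecord,
    SpotMap,
    TractSet,
    VolumeGrid,
    make_grid,
)
from .scores import responder_category
from .vta import Lead, VTAModel, patient_vta, vta_radius

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "table1_fixture",
    "table1_csv",
    "default_grid",
    "sphere_volume",
    "synthetic_spot",
    "generate_cohort",
    "generate_landmarks",
    "landmarks_for_severity",
    "generate_tracts",
]

#: Nominal right-hemisphere GPi stimulation target (MNI mm).
GPI_TARGET = np.array([20.0, -12.0, -4.0])


# ---------------------------------------------------------------------------
# printed prospective cohort table

# columns: id, sex, type, onset, surgery, duration, brady_full, brady_half,
#          tsui_full, tsui_half, amplitude mA, pulse width us, frequency Hz
_TABLE1_ROWS = [
    ("P01", "f", "CER", 36, 45, 10, 9.5, 7.0, 4.0, 3.0, 6.80, 90, 179),
    ("P02", "m", "CER", 33, 61, 28, 8.5, 5.5, 10.5, 8.5, 4.70, 90, 179),
    ("P03", "f", "CER", 18, 45, 27, 6.0, 7.0, 5.5, 4.0, 2.45, 60, 180),
    ("P04", "f", "CER", 50, 60, 10, 13.0, 9.0, 3.0, 5.0, 3.80, 40, 179),
    ("P05", "m", "SEG", 44, 46, 2, 14.5, 10.5, 0.5, 1.5, 3.80, 120, 170),
    ("P06", "f", "SEG", 50, 52, 2, 5.5, 6.5, 2.5, 6.5, 2.65, 90, 180),
    ("P07", "f", "CER", 4, 63, 59, 8.0, 8.0, 2.5, 2.5, 4.00, 90, 130),
    ("P08", "f", "CER", 61, 65, 4, 18.0, 17.0, 4.0, 6.5, 5.25, 90, 180),
    ("P09", "f", "CER", 55, 56, 1, 20.5, 20.0, 3.0, 3.0, 3.40, 60, 180),
    ("P10", "f", "CER", 39, 64, 25, 10.5, 10.0, 4.5, 4.5, 4.00, 60, 179),
    ("P11", "f", "CER", 50, 64, 9, 14.5, 9.5, 2.5, 3.4, 4.10, 120, 130),
]

_SEX = {"f": "female", "m": "male"}
_TYPE = {"CER": "cervical", "SEG": "segmental"}


def table1_fixture() -> list[PatientRecord]:
    """The 11-patient prospective cohort table as records.

    The per-condition bradykinesia item sums (MDS-UPDRS III items 3.4-3.8
    under full and half stimulation) and TSUI scores are carried in
    ``record.extra`` as ``bradykinesia_full``/``bradykinesia_half`` and
    ``tsui_full``/``tsui_half``.
    """
    records = []
    for (pid, sex, dt, onset, surgery, dur, bf, bh, tf, th, amp, pw, fr) in _TABLE1_ROWS:
        records.append(
            PatientRecord(
                patient_id=pid,
                sex=_SEX[sex],
                dystonia_type=_TYPE[dt],
                age_onset=float(onset),
                age_surgery=float(surgery),
                disease_duration=float(dur),
                amplitude_ma=float(amp),
                pulse_width_us=float(pw),
                frequency_hz=float(fr),
                extra={
                    "bradykinesia_full": bf,
                    "bradykinesia_half": bh,
                    "tsui_full": tf,
                    "tsui_half": th,
                },
            )
        )
    return records


def table1_csv(path) -> None:
    """Write the fixture as a cohort CSV (canonical header plus extras)."""
    from .data_model import write_cohort_csv

    write_cohort_csv(table1_fixture(), path)


# ---------------------------------------------------------------------------
# synthetic retrospective cohort

@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs for the synthetic retrospective cohort.

    Stimulation parameters are sampled around the retrospective cohort's
    distribution (amplitude 3.4 +- 1.1 mA, pulse width 112 +- 43 us,
    frequency 153 +- 24 Hz).  The sour sphere sits posterolateral to the
    sweet sphere at the pallidal target, 3-4 mm away, so that recovered
    sour and sweet spots are spatially segregated.  ``effect_beta`` is in
    severity units per unit overlap fraction; defaults give a planted
    signal of roughly half the noise variance, i.e. a recoverable but
    realistically noisy anatomical effect.
    """

    n_patients: int = 60
    sour_center: tuple[float, float, float] = (22.0, -10.0, -6.0)
    sour_radius: float = 3.0
    sweet_center: tuple[float, float, float] = (20.0, -12.0, -4.0)
    sweet_radius: float = 3.0
    effect_beta: float = 1.5
    sex_effect: float = 0.25
    onset_slope: float = 0.01
    noise_sd: float = 0.4
    jitter_sd: float = 1.0
    amplitude_mean: float = 3.4
    amplitude_sd: float = 1.1
    pulse_width_mean: float = 112.0
    pulse_width_sd: float = 43.0
    frequency_mean: float = 153.0
    frequency_sd: float = 24.0
    p_female: float = 0.49
    grid_spacing: float = 0.5


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    leads: dict[str, dict[str, Lead]]
    vta_sets: list[list]
    severity: np.ndarray
    overlap_fraction: np.ndarray
    grid: VolumeGrid
    truth: dict
    n_resampled: int = 0


def default_grid(spacing: float = 0.5) -> VolumeGrid:
    """Right-hemisphere analysis grid around the pallidal target.

    Spans 8..32 mm in x, -26..0 in y and -20..12 in z, generous enough for
    all four lead contacts plus a maximal (6 mm) VTA.
    """
    origin = np.array([8.0, -26.0, -20.0])
    extent = np.array([24.0, 26.0, 32.0])
    shape = np.round(extent / spacing).astype(int) + 1
    return make_grid(origin, shape, spacing)


def sphere_volume(grid: VolumeGrid, center, radius: float) -> np.ndarray:
    """Boolean array of grid voxels whose centres lie in the sphere."""
    from .vta import _sphere_mask

    return _sphere_mask(grid, np.asarray(center, float), radius).astype(bool)


def synthetic_spot(
    grid: VolumeGrid, center, radius: float, polarity: str, weight: float = 1.0
) -> SpotMap:
    """A uniform-weight spherical spot map (e.g. a stand-in sweet spot)."""
    mask = sphere_volume(grid, center, radius)
    return SpotMap(
        mask=grid.like(mask.astype(float)),
        weight=grid.like(np.where(mask, weight, 0.0)),
        polarity=polarity,
        cluster_table=[{
            "cluster_id": 1, "voxel_count": int(mask.sum()),
            "centroid_mm": list(map(float, center)), "peak_abs_t": weight,
        }],
    )


def generate_cohort(
    config: SyntheticConfig, seed: int, model: VTAModel = VTAModel()
) -> SyntheticCohort:
    """Simulate a bilateral pallidal DBS cohort with a planted sour region.

    Active contacts land at the nominal GPi target plus isotropic Gaussian
    jitter (left hemisphere mirrored); per-side settings are sampled from
    the configured distributions.  Severity (a BDS-like continuous outcome)
    is

        effect_beta * (fraction of the sour sphere covered by the pooled VTA)
        + sex_effect * [female] + onset_slope * (age_onset - 37) + noise,

    and dystonia improvement is drawn from the overlap with the sweet
    sphere, yielding responder categories.  Contacts jittered too far for
    their maximal VTA to stay on the grid are resampled (count reported).
    """
    rng = np.random.default_rng(seed)
    grid = default_grid(config.grid_spacing)
    sour = sphere_volume(grid, config.sour_center, config.sour_radius).ravel()
    sweet = sphere_volume(grid, config.sweet_center, config.sweet_radius).ravel()

    records: list[PatientRecord] = []
    leads: dict[str, dict[str, Lead]] = {}
    vta_sets = []
    overlap = np.empty(config.n_patients)
    sweet_overlap = np.empty(config.n_patients)
    severity = np.empty(config.n_patients)
    n_resampled = 0

    for i in range(config.n_patients):
        pid = f"S{i:03d}"
        sex = "female" if rng.random() < config.p_female else "male"
        onset = float(np.clip(rng.normal(37, 15), 5, 70))
        duration = float(np.clip(rng.normal(12, 8), 1, 40))
        settings = {}
        pleads = {}
        for side in ("right", "left"):
            while True:
                jitter = rng.normal(0, config.jitter_sd, size=3)
                if np.all(np.abs(jitter) <= 4.5):
                    break
                n_resampled += 1
            contact_center = GPI_TARGET + jitter
            active = int(rng.integers(1, 3))
            direction = np.array([0.0, 0.0, 1.0])
            tip = contact_center - active * 2.0 * direction
            if side == "left":
                tip = tip * np.array([-1.0, 1.0, 1.0])
            pleads[side] = Lead(tip=tip, direction=direction)
            settings[side] = HemisphereSetting(
                active_contact=active,
                amplitude_ma=float(np.clip(
                    rng.normal(config.amplitude_mean, config.amplitude_sd), 0.5, 6.0)),
                pulse_width_us=float(np.clip(
                    rng.normal(config.pulse_width_mean, config.pulse_width_sd), 40, 210)),
                frequency_hz=float(np.clip(
                    rng.normal(config.frequency_mean, config.frequency_sd), 60, 250)),
            )
        record = PatientRecord(
            patient_id=pid,
            sex=sex,
            dystonia_type=str(rng.choice(
                ["cervical", "segmental", "generalized"], p=[0.5, 0.25, 0.25])),
            age_onset=onset,
            age_surgery=onset + duration,
            disease_duration=duration,
            amplitude_ma=float(np.mean([s.amplitude_ma for s in settings.values()])),
            pulse_width_us=float(np.mean([s.pulse_width_us for s in settings.values()])),
            frequency_hz=float(np.mean([s.frequency_hz for s in settings.values()])),
            hemisphere_settings=settings,
        )
        vtas = patient_vta(record, pleads, grid, model=model, mirror_left=True)
        union = np.zeros(grid.shape, dtype=bool).ravel()
        for v in vtas:
            union |= v.mask.values.ravel().astype(bool)
        # overlap fraction = covered share of the planted sphere: grid-free,
        # and monotone in VTA size, which carries the pulse-width mechanism
        frac = float(union[sour].sum() / sour.sum())
        sfrac = float(union[sweet].sum() / sweet.sum())
        sev = (
            config.effect_beta * frac
            + config.sex_effect * (sex == "female")
            + config.onset_slope * (onset - 37)
            + rng.normal(0, config.noise_sd)
        )
        improvement = float(np.clip(0.2 + 1.2 * sfrac + rng.normal(0, 0.15), -1, 1))
        record.bds = sev
        record.dystonia_improvement = improvement
        record.responder_category = responder_category(improvement)
        records.append(record)
        leads[pid] = pleads
        vta_sets.append(vtas)
        overlap[i] = frac
        sweet_overlap[i] = sfrac
        severity[i] = sev

    truth = {
        "sour_center": list(config.sour_center),
        "sour_radius": config.sour_radius,
        "sweet_center": list(config.sweet_center),
        "sweet_radius": config.sweet_radius,
        "effect_beta": config.effect_beta,
        "sex_effect": config.sex_effect,
        "onset_slope": config.onset_slope,
        "noise_sd": config.noise_sd,
        "seed": seed,
    }
    return SyntheticCohort(
        records=records, leads=leads, vta_sets=vta_sets, severity=severity,
        overlap_fraction=overlap, grid=grid, truth=truth, n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# synthetic hand landmarks

# static template (image px); landmark 8 (tap) and fingertips (open) animate
_HAND_TEMPLATE = np.array([
    (0, 0),        # 0 wrist
    (40, 0), (80, 0), (120, 0), (160, 0),          # 1-4 thumb chain (len 120)
    (35, 80), (40, 115), (43, 140), (45, 160),     # 5-8 index
    (10, 85), (12, 125), (13, 155), (14, 180),     # 9-12 middle
    (-15, 82), (-18, 120), (-20, 148), (-21, 170), # 13-16 ring
    (-40, 75), (-45, 105), (-48, 128), (-50, 145), # 17-20 little
], dtype=float)

_THUMB_LENGTH = 120.0
_FINGER_LENGTH = 80.0


def _envelope(t: np.ndarray, freq_hz: float, amplitude: float, decay: float) -> np.ndarray:
    cycle = np.floor(freq_hz * t)
    return amplitude * np.clip(1.0 - decay * cycle, 0.0, None) * (
        0.5 - 0.5 * np.cos(2 * np.pi * freq_hz * t)
    )


def generate_landmarks(
    task: str,
    freq_hz: float,
    amplitude: float,
    decay_per_cycle: float = 0.0,
    noise_sd: float = 0.0,
    fps: float = 60.0,
    duration_s: float = 10.0,
    seed: int = 0,
) -> LandmarkSeries:
    """Synthesize a 21-point hand landmark series for one task.

    The driven signal is ``v(t) = A * (1 - decay * cycle(t)) *
    (0.5 - 0.5 cos(2 pi f t))`` — for finger tapping ``A`` is the
    thumb-index distance as a fraction of the thumb length; for hand
    opening ``A`` is the MCP angle excursion in degrees above a 95 degree
    baseline.  Gaussian jitter of ``noise_sd`` image units is added to every
    landmark coordinate.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be > 0")
    if fps <= 2 * freq_hz:
        raise ValueError(
            f"fps={fps} violates the Nyquist bound for freq={freq_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    v = _envelope(t, freq_hz, amplitude, decay_per_cycle)
    frames = np.tile(_HAND_TEMPLATE, (n, 1, 1))
    if task == "finger_tap":
        # index tip moves perpendicular to the thumb axis
        frames[:, 8, 0] = _HAND_TEMPLATE[4, 0]
        frames[:, 8, 1] = _HAND_TEMPLATE[4, 1] + v * _THUMB_LENGTH
    elif task == "hand_open":
        theta = np.radians(np.clip(95.0 + v, 0.0, 179.0))  # interior MCP angle
        from .data_model import FINGER_MCP, FINGER_TIP, WRIST

        for finger, mcp in FINGER_MCP.items():
            u = _HAND_TEMPLATE[WRIST] - _HAND_TEMPLATE[mcp]
            u = u / np.linalg.norm(u)
            cos_t, sin_t = np.cos(theta), np.sin(theta)
            # rotate u by theta; interior angle at the MCP equals theta
            rot = np.stack([
                cos_t * u[0] - sin_t * u[1],
                sin_t * u[0] + cos_t * u[1],
            ], axis=1)
            frames[:, FINGER_TIP[finger]] = _HAND_TEMPLATE[mcp] + _FINGER_LENGTH * rot
    else:
        raise ValueError(f"invalid task {task!r}")
    if noise_sd > 0:
        frames = frames + rng.normal(0, noise_sd, size=frames.shape)
    return LandmarkSeries(fps=fps, frames=frames, task=task)


def landmarks_for_severity(
    severity: float,
    task: str = "finger_tap",
    fps: float = 60.0,
    duration_s: float = 10.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> LandmarkSeries:
    """Landmark series whose kinematics degrade with a bradykinesia level.

    ``severity`` in [0, 1] maps to slower (3.0 -> 1.5 Hz), smaller and more
    decrementing movements, mimicking the parkinsonian phenotype.
    """
    s = float(np.clip(severity, 0.0, 1.0))
    freq = 3.0 - 1.5 * s
    amp = (0.9 - 0.5 * s) if task == "finger_tap" else (70.0 - 35.0 * s)
    decay = 0.12 * s
    return generate_landmarks(
        task, freq, amp, decay_per_cycle=decay, noise_sd=noise_sd,
        fps=fps, duration_s=duration_s, seed=seed,
    )


# ---------------------------------------------------------------------------
# synthetic streamline bundles

def generate_tracts(
    clearances_mm: dict[str, float],
    target_mm=GPI_TARGET,
    n_streamlines: int = 100,
    length_mm: float = 60.0,
    spread_mm: float = 0.5,
    seed: int = 0,
) -> TractSet:
    """Straight bundles passing at known clearances from the target.

    Each tract is a bundle of ``n_streamlines`` lines parallel to z,
    offset from the target in +y by ``clearance + |N(0, spread)|`` (the
    half-normal keeps every streamline at least ``clearance`` away) with a
    bounded lateral scatter in x; so the closest approach to the target is
    controlled exactly.
    """
    rng = np.random.default_rng(seed)
    target = np.asarray(target_mm, dtype=float)
    out = TractSet()
    z = np.array([-length_mm / 2, 0.0, length_mm / 2])
    for name, clearance in clearances_mm.items():
        lines = []
        for _ in range(n_streamlines):
            dy = clearance + min(abs(rng.normal(0, spread_mm)), 2.0)
            dx = float(np.clip(rng.normal(0, spread_mm), -2.0, 2.0))
            pts = np.stack([
                np.full(3, target[0] + dx),
                np.full(3, target[1] + dy),
                target[2] + z,
            ], axis=1)
            lines.append(pts)
        out[name] = lines
    return out
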