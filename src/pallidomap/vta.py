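"""Volume of tissue activated (VTA) construction.

VTAs are modelled as spheres centred on the active contact, with a
parametric radius that grows monotonically with stimulation amplitude and
pulse width,

    r(A, pw) = k1 * sqrt(A) * (pw / 60 us)^k2,     clamped to [0, r_max],

with defaults k1 = 1.5 mm, k2 = 0.3, r_max = 6 mm.  This deliberately simple
activation model preserves the two properties the downstream mapping
consumes — the location of stimulation and its monotone growth with
amplitude and pulse width — without attempting biophysical field modelling.
Multi-contact configurations form the union of one sphere per active
contact.

Left-hemisphere VTAs can be mirrored through the midsagittal plane
(x -> -x in MNI RAS coordinates) so that bilateral leads can be pooled on a
single right-hemisphere grid, doubling the per-voxel sample size for the
probabilistic maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import VTA, HemisphereSetting, PatientRecord, VolumeGrid

__all__ = [
    "VTAModel",
    "Lead",
    "contact_positions",
    "vta_radius",
    "voxelize_vta",
    "mirror_to_right",
    "patient_vta",
]


@dataclass(frozen=True)
class VTAModel:
    """Parameters of the parametric radius model."""

    k1_mm: float = 1.5
    k2: float = 0.3
    reference_pw_us: float = 60.0
    max_radius_mm: float = 6.0


@dataclass(frozen=True)
class Lead:
    """A quadripolar DBS lead: contact k sits at tip + k * spacing * direction."""

    tip: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    contact_spacing: float = 2.0
    n_contacts: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("lead direction must be non-zero")
        object.__setattr__(self, "direction", d / norm)
        if self.contact_spacing <= 0:
            raise ValueError("contact spacing must be > 0")


def contact_positions(lead: Lead) -> np.ndarray:
    """Centres of the lead's contacts, shape (n_contacts, 3), in mm."""
    ks = np.arange(lead.n_contacts)[:, None]
    return lead.tip[None, :] + ks * lead.contact_spacing * lead.direction[None, :]


def vta_radius(
    amplitude_ma: float, pulse_width_us: float, model: VTAModel = VTAModel()
) -> float:
    """Activation radius (mm) for a stimulation setting."""
    if amplitude_ma < 0 or pulse_width_us <= 0:
        raise ValueError("amplitude must be >= 0 and pulse width > 0")
    r = (
        model.k1_mm
        * np.sqrt(amplitude_ma)
        * (pulse_width_us / model.reference_pw_us) ** model.k2
    )
    return float(np.clip(r, 0.0, model.max_radius_mm))


def _sphere_mask(grid: VolumeGrid, center: np.ndarray, radius: float) -> np.ndarray:
    """Binary array of voxels whose centres lie within ``radius`` of ``center``.

    A radius below half the voxel spacing still activates the single nearest
    voxel, so every programmed setting produces a non-empty VTA.
    """
    center = np.asarray(center, dtype=float)
    cv = grid.world_to_voxel(center)[0]
    shape = np.asarray(grid.shape)
    if np.any(cv < -0.5) or np.any(cv > shape - 0.5):
        raise ValueError(f"VTA centre {center} lies outside the grid")
    mask = np.zeros(grid.shape, dtype=np.uint8)
    spacing = grid.spacing
    if radius < spacing.min() / 2:
        idx = np.clip(np.round(cv).astype(int), 0, shape - 1)
        mask[tuple(idx)] = 1
        return mask
    # bounding box in voxel space, then exact distance test in world mm
    rad_vox = radius / spacing
    lo = np.maximum(np.floor(cv - rad_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(cv + rad_vox + 1).astype(int), shape - 1)
    ii, jj, kk = np.meshgrid(
        *[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"
    )
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = grid.voxel_to_world(ijk)
    inside = np.sum((world - center) ** 2, axis=1) <= radius**2
    sub = inside.reshape(ii.shape)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = sub
    return mask


def voxelize_vta(
    center: np.ndarray,
    radius: float,
    grid: VolumeGrid,
    patient_id: str = "",
    side: str = "right",
    settings: HemisphereSetting | None = None,
) -> VTA:
    """Rasterize a spherical VTA onto ``grid``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = _sphere_mask(grid, center, radius)
    return VTA(
        patient_id=patient_id,
        side=side,
        center=np.asarray(center, dtype=float),
        radius=float(radius),
        mask=grid.like(mask),
        source_settings=settings,
    )


def mirror_to_right(obj, grid: VolumeGrid | None = None):
    """Mirror a point or VTA through the midsagittal plane (x -> -x).

    For a VTA the mirrored sphere is re-voxelized on ``grid`` (defaults to
    the VTA's own grid), so bilateral leads can be pooled on one
    right-hemisphere grid.
    """
    if isinstance(obj, VTA):
        target = grid if grid is not None else obj.mask
        new_center = obj.center * np.array([-1.0, 1.0, 1.0])
        new_side = "right" if obj.side == "left" else "left"
        return voxelize_vta(
            new_center,
            obj.radius,
            target,
            patient_id=obj.patient_id,
            side=new_side,
            settings=obj.source_settings,
        )
    pt = np.asarray(obj, dtype=float)
    return pt * np.array([-1.0, 1.0, 1.0])


def patient_vta(
    record: PatientRecord,
    leads: dict[str, Lead],
    grid: VolumeGrid,
    model: VTAModel = VTAModel(),
    mirror_left: bool = True,
) -> list[VTA]:
    """One VTA per implanted side, pooled onto the (right-hemisphere) grid.

    Each side's VTA is a sphere at its active contact with the radius of
    that side's amplitude/pulse-width setting; left-side VTAs are mirrored
    to the right when ``mirror_left`` is set.
    """
    if not record.hemisphere_settings:
        raise ValueError(f"{record.patient_id}: no hemisphere settings")
    vtas: list[VTA] = []
    for side, setting in record.hemisphere_settings.items():
        if side not in leads:
            raise ValueError(f"{record.patient_id}: no lead geometry for side {side}")
        lead = leads[side]
        if not 0 <= setting.active_contact < lead.n_contacts:
            raise ValueError(
                f"{record.patient_id}/{side}: active contact {setting.active_contact} "
                f"outside 0..{lead.n_contacts - 1}"
            )
        center = contact_positions(lead)[setting.active_contact]
        radius = vta_radius(setting.amplitude_ma, setting.pulse_width_us, model)
        if side == "left" and mirror_left:
            center = mirror_to_right(center)
        vtas.append(
            voxelize_vta(
                center, radius, grid,
                patient_id=record.patient_id, side=side, settings=setting,
            )
        )
    return vtas
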