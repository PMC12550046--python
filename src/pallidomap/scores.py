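"""Bespoke bradykinesia scoring.

The cohort is rated on the bradykinesia-related MDS-UPDRS III items
(finger tapping, hand movements, pronation/supination, toe tapping, leg
agility; items 3.4-3.8), but retrospective video material rarely allows all
items to be rated.  The Normalized Bradykinesia Score (NBS) therefore
averages whatever subitems were usable,

    NBS = sum(subitem scores) / number of subitems used,

and the Bradykinesia Difference Score is the postoperative change,

    BDS = NBS_post - NBS_pre,

so BDS > 0 means parkinsonian features worsened after surgery.  Any strictly
positive BDS counts as worsening for the binarized analyses.  Neither score
has undergone formal clinimetric validation; they are normalization devices
for heterogeneous ratings.
"""

from __future__ import annotations

import math
from typing import Sequence

from .data_model import PatientRecord, SubitemRating

__all__ = [
    "nbs",
    "bds",
    "worsened",
    "responder_category",
    "teed",
    "score_record",
]


def nbs(subitems: Sequence[SubitemRating]) -> float:
    """Normalized Bradykinesia Score: mean of the rated subitem scores."""
    if len(subitems) == 0:
        raise ValueError("NBS undefined for an empty subitem list")
    return sum(s.score for s in subitems) / len(subitems)


def bds(nbs_pre: float, nbs_post: float) -> float:
    """Bradykinesia Difference Score: post minus pre NBS."""
    for name, v in (("nbs_pre", nbs_pre), ("nbs_post", nbs_post)):
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be a finite number")
        if not 0 <= v <= 4:
            raise ValueError(f"{name} must lie in [0, 4], got {v}")
    return nbs_post - nbs_pre


def worsened(bds_value: float) -> bool:
    """Binarized outcome: any strictly positive BDS counts as worsening."""
    if not math.isfinite(bds_value):
        raise ValueError("bds must be finite")
    return bds_value > 0


def responder_category(improvement_fraction: float) -> str:
    """Dystonia response category from fractional motor improvement.

    Bins: non (<25%), average (25-50%), good (50-80%), super (>=80%).
    The upper edge of each bin is left-closed (0.80 -> super).
    """
    if not math.isfinite(improvement_fraction):
        raise ValueError("improvement fraction must be finite")
    if improvement_fraction < 0.25:
        return "non"
    if improvement_fraction < 0.50:
        return "average"
    if improvement_fraction < 0.80:
        return "good"
    return "super"


def teed(
    amplitude_ma: float,
    pulse_width_us: float,
    frequency_hz: float,
    impedance_ohm: float | None = None,
) -> float:
    """Total electrical energy delivered per second, in microjoules.

    TEED = I^2 * R * pulse_width * frequency * 1 s.  Current-controlled
    systems do not report an impedance, so ``impedance_ohm`` must be passed
    explicitly; there is no silent default.
    """
    if impedance_ohm is None:
        raise ValueError(
            "impedance_ohm is required: pass an explicit impedance assumption "
            "(e.g. 1000 Ohm) for current-controlled systems"
        )
    if amplitude_ma < 0 or pulse_width_us <= 0 or frequency_hz <= 0 or impedance_ohm <= 0:
        raise ValueError("stimulation parameters must be positive (amplitude >= 0)")
    amps = amplitude_ma * 1e-3
    seconds = pulse_width_us * 1e-6
    joules = amps**2 * impedance_ohm * seconds * frequency_hz * 1.0
    return joules * 1e6  # -> microjoules


def score_record(record: PatientRecord) -> PatientRecord:
    """Fill nbs_pre/nbs_post/bds on a record that carries subitem ratings."""
    if not record.subitems_pre or not record.subitems_post:
        raise ValueError(
            f"{record.patient_id}: pre and post subitem ratings are required for NBS"
        )
    record.nbs_pre = nbs(record.subitems_pre)
    record.nbs_post = nbs(record.subitems_post)
    record.bds = bds(record.nbs_pre, record.nbs_post)
    return record
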