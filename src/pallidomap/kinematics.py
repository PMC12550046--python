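"""Markerless hand-kinematics features for bradykinesia.

Two tasks are analyzed from 21-point 2D hand landmark series:

* finger tapping — the thumb-index fingertip distance, normalized to the
  length of the thumb so that the signal is scale-free;
* hand opening — the interior angle at each finger's metacarpophalangeal
  (MCP) joint, formed by the wrist, the MCP and the fingertip (degrees;
  angles are inherently scale-free).

From each signal, five features are extracted per task: movement frequency,
amplitude, speed, amplitude decay and velocity decay.  Cycle segmentation
uses local-extremum detection on a low-pass filtered copy of the signal;
decays are least-squares slopes across cycles normalized to the first
cycle, so they read as fractional decrement per cycle (negative = fading
movements, the parkinsonian sequence effect).

All cut-offs live in :class:`KinematicsConfig`; the defaults are chosen for
hand movements in the 1-4 Hz band typical of tapping tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_model import (
    FINGER_MCP,
    FINGER_TIP,
    INDEX_TIP,
    THUMB_CHAIN,
    THUMB_TIP,
    WRIST,
    LandmarkSeries,
)

__all__ = [
    "KinematicsConfig",
    "KinematicSignal",
    "Cycle",
    "KinematicFeatures",
    "fingertap_signal",
    "handopen_signal",
    "detect_cycles",
    "extract_features",
]


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunables for cycle detection and feature extraction.

    lowpass_cutoff_hz : cut-off of the 4th-order zero-phase Butterworth
        filter applied before peak picking (hand movements live well below
        6 Hz; the filter only serves extremum detection, features are
        measured on the raw signal).
    prominence_fraction : required peak prominence as a fraction of the
        5th-95th percentile signal range.
    min_cycles_for_decay : decay slopes are unreliable below 3 cycles and
        left unset there.
    """

    lowpass_cutoff_hz: float = 6.0
    prominence_fraction: float = 0.15
    min_cycles_for_decay: int = 3


@dataclass
class KinematicSignal:
    """A 1D kinematic time series (normalized distance or joint angle)."""

    t: np.ndarray  # seconds
    v: np.ndarray  # normalized units or degrees
    task: str
    signal_kind: str  # tap_distance / open_angle

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.size < 2:
            raise ValueError("t and v must be equal-length with >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class Cycle:
    peak_time: float
    trough_time: float
    excursion: float  # peak-to-trough amplitude
    peak_index: int
    trough_index: int
    end_index: int  # index of the next peak (cycle end)


@dataclass
class KinematicFeatures:
    frequency: float  # Hz
    amplitude: float  # signal units
    speed: float  # signal units / s
    amplitude_decay: float | None  # fraction per cycle
    velocity_decay: float | None  # fraction per cycle
    n_cycles: int

    def as_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "amplitude": self.amplitude,
            "speed": self.speed,
            "amplitude_decay": self.amplitude_decay,
            "velocity_decay": self.velocity_decay,
            "n_cycles": self.n_cycles,
        }


# ---------------------------------------------------------------------------
# signals

def fingertap_signal(series: LandmarkSeries) -> KinematicSignal:
    """Thumb-index fingertip distance, normalized to the thumb length.

    The thumb length is the summed segment length along the thumb chain
    (CMC->MCP->IP->tip), computed per frame and summarized by its median so
    that landmark jitter in single frames cannot rescale the whole signal.
    """
    if series.task != "finger_tap":
        raise ValueError(f"expected a finger_tap series, got task={series.task!r}")
    pts = series.frames
    dist = np.linalg.norm(pts[:, THUMB_TIP] - pts[:, INDEX_TIP], axis=1)
    seg = np.zeros(series.n_frames)
    for a, b in zip(THUMB_CHAIN[:-1], THUMB_CHAIN[1:]):
        seg += np.linalg.norm(pts[:, b] - pts[:, a], axis=1)
    thumb_len = float(np.median(seg))
    if thumb_len <= 0:
        raise ValueError("thumb length is zero; cannot normalize tap distance")
    return KinematicSignal(series.times, dist / thumb_len, series.task, "tap_distance")


def _mcp_angles(pts: np.ndarray, mcp: int, tip: int) -> np.ndarray:
    """Interior angle (degrees) at the MCP between (MCP->wrist) and (MCP->tip)."""
    u = pts[:, WRIST] - pts[:, mcp]
    w = pts[:, tip] - pts[:, mcp]
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bad = (nu == 0) | (nw == 0)
    if bad.any():
        if bad.all():
            raise ValueError("all frames degenerate (coincident landmarks)")
        idx = np.arange(len(ang))
        ang[bad] = np.interp(idx[bad], idx[~bad], ang[~bad])
    return ang


def handopen_signal(series: LandmarkSeries) -> dict[str, KinematicSignal]:
    """MCP extension angles for the four fingers, plus their mean.

    Returns ``{"index": .., "middle": .., "ring": .., "little": .., "mean": ..}``
    with angles in [0, 180] degrees (180 = finger fully in line with the
    forearm axis through the wrist).  Degenerate frames (coincident points)
    are interpolated from their neighbours.
    """
    if series.task != "hand_open":
        raise ValueError(f"expected a hand_open series, got task={series.task!r}")
    out: dict[str, KinematicSignal] = {}
    stack = []
    for finger, mcp in FINGER_MCP.items():
        ang = _mcp_angles(series.frames, mcp, FINGER_TIP[finger])
        out[finger] = KinematicSignal(series.times, ang, series.task, "open_angle")
        stack.append(ang)
    out["mean"] = KinematicSignal(
        series.times, np.mean(stack, axis=0), series.task, "open_angle"
    )
    return out


# ---------------------------------------------------------------------------
# cycle detection

def _lowpass(v: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq * 0.99:
        return v  # already band-limited by sampling
    b, a = sps.butter(4, cutoff_hz / nyq)
    # filtfilt needs some run-in; fall back to the raw signal for tiny series
    if len(v) <= 3 * max(len(a), len(b)):
        return v
    return sps.filtfilt(b, a, v)


def detect_cycles(
    signal: KinematicSignal, config: KinematicsConfig = KinematicsConfig()
) -> list[Cycle]:
    """Segment a repetitive movement signal into peak-to-peak cycles.

    Peaks are local maxima of a low-pass filtered copy with prominence at
    least ``prominence_fraction`` of the robust (5th-95th percentile) signal
    range; each cycle spans consecutive peaks and its excursion is the peak
    value minus the minimum of the raw signal inside the span.  A constant
    signal yields zero cycles.
    """
    t, v = signal.t, signal.v
    if t[-1] - t[0] < 2.0:
        raise ValueError("need at least 2 s of signal for cycle detection")
    lo, hi = np.percentile(v, [5, 95])
    vrange = hi - lo
    if vrange <= 0:
        return []
    smooth = _lowpass(v, signal.fs, config.lowpass_cutoff_hz)
    peaks, _ = sps.find_peaks(smooth, prominence=config.prominence_fraction * vrange)
    if len(peaks) < 2:
        return []
    cycles: list[Cycle] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = v[p0 : p1 + 1]
        trough_rel = int(np.argmin(seg))
        trough = p0 + trough_rel
        cycles.append(
            Cycle(
                peak_time=float(t[p0]),
                trough_time=float(t[trough]),
                excursion=float(v[p0] - v[trough]),
                peak_index=int(p0),
                trough_index=int(trough),
                end_index=int(p1),
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# features

def _decay_slope(values: np.ndarray) -> float:
    """Least-squares slope across cycle index, normalized to the first value."""
    idx = np.arange(len(values), dtype=float)
    slope = np.polyfit(idx, values, 1)[0]
    first = values[0]
    if first == 0:
        return float("nan")
    return float(slope / first)


def extract_features(
    signal: KinematicSignal, config: KinematicsConfig = KinematicsConfig()
) -> KinematicFeatures:
    """Compute the five bradykinesia features of one movement signal.

    frequency   cycles per second between the first and last detected peak
    amplitude   mean peak-to-trough excursion per cycle
    speed       mean |dv/dt| (central differences) over the cycling window
    amplitude_decay, velocity_decay
                normalized least-squares slopes of per-cycle excursion and
                per-cycle peak |dv/dt| across cycles (fraction/cycle);
                unset below ``min_cycles_for_decay`` cycles
    """
    cycles = detect_cycles(signal, config)
    n = len(cycles)
    if n == 0:
        return KinematicFeatures(0.0, 0.0, 0.0, None, None, 0)
    t, v = signal.t, signal.v
    first_peak = cycles[0].peak_index
    last_peak = cycles[-1].end_index
    freq = n / (t[last_peak] - t[first_peak])

    excursions = np.array([c.excursion for c in cycles])
    amplitude = float(np.mean(excursions))

    dv = np.gradient(v, t)
    speed = float(np.mean(np.abs(dv[first_peak : last_peak + 1])))

    amp_decay = vel_decay = None
    if n >= config.min_cycles_for_decay:
        amp_decay = _decay_slope(excursions)
        peak_speeds = [
            np.max(np.abs(dv[c.peak_index : c.end_index + 1])) for c in cycles
        ]
        vel_decay = _decay_slope(np.asarray(peak_speeds))
    return KinematicFeatures(
        frequency=float(freq),
        amplitude=amplitude,
        speed=speed,
        amplitude_decay=amp_decay,
        velocity_decay=vel_decay,
        n_cycles=n,
    )
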