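"""Kinematic signals, cycle detection and bradykinesia features."""

import numpy as np
import pytest
import scipy.stats

from pallidomap.data_model import FINGER_MCP, FINGER_TIP, WRIST, LandmarkSeries
from pallidomap.kinematics import (
    KinematicSignal,
    detect_cycles,
    extract_features,
    fingertap_signal,
    handopen_signal,
)
from pallidomap.synthetic_data import (
    generate_landmarks,
    landmarks_for_severity,
)


def _sine_signal(freq=2.0, duration=10.0, fps=60.0, offset=0.5, amp=0.4, noise=0.0,
                 seed=0):
    t = np.arange(int(duration * fps)) / fps
    v = offset + amp * np.sin(2 * np.pi * freq * t)
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise * amp, len(t))
    return KinematicSignal(t, v, "finger_tap", "tap_distance")


class TestTapSignal:
    def test_normalized_by_thumb_length(self):
        series = generate_landmarks("finger_tap", 2.0, 0.8, fps=60, duration_s=5)
        sig = fingertap_signal(series)
        assert sig.v.min() >= -1e-9
        assert sig.v.max() == pytest.approx(0.8, abs=0.02)

    def test_constant_hand_gives_constant_signal(self):
        series = generate_landmarks("finger_tap", 2.0, 0.0, fps=60, duration_s=3)
        sig = fingertap_signal(series)
        assert np.ptp(sig.v) < 1e-12

    def test_scale_invariance(self):
        series = generate_landmarks("finger_tap", 2.0, 0.8, noise_sd=0.5,
                                    fps=60, duration_s=5, seed=7)
        scaled = LandmarkSeries(series.fps, series.frames * 2.0, series.task)
        assert np.allclose(fingertap_signal(series).v, fingertap_signal(scaled).v)

    def test_wrong_task_rejected(self):
        series = generate_landmarks("hand_open", 2.0, 60.0, fps=60, duration_s=3)
        with pytest.raises(ValueError):
            fingertap_signal(series)


class TestOpenSignal:
    def test_angles_match_atan2_oracle(self):
        rng = np.random.default_rng(11)
        frames = rng.uniform(-100, 100, size=(20, 21, 2))
        series = LandmarkSeries(60.0, frames, "hand_open")
        signals = handopen_signal(series)
        for finger, mcp in FINGER_MCP.items():
            tip = FINGER_TIP[finger]
            for t in range(20):
                u = frames[t, WRIST] - frames[t, mcp]
                w = frames[t, tip] - frames[t, mcp]
                cross = u[0] * w[1] - u[1] * w[0]
                ang = np.degrees(abs(np.arctan2(cross, np.dot(u, w))))
                assert signals[finger].v[t] == pytest.approx(ang, abs=1e-9)

    def test_collinear_and_perpendicular(self):
        frames = np.tile(np.zeros((21, 2)), (2, 1, 1))
        frames[:, WRIST] = (0, -10)
        frames[:, FINGER_MCP["index"]] = (0, 0)
        frames[:, FINGER_TIP["index"]] = (0, 10)       # collinear -> 180
        frames[:, FINGER_MCP["middle"]] = (5, 0)
        frames[:, FINGER_TIP["middle"]] = (15, 0)      # perpendicular? compute
        # wrist-mcp vector (-5,-10); tip vector (10, 0) -> not 90; use exact
        frames[:, FINGER_MCP["ring"]] = (0, 0)
        frames[:, FINGER_TIP["ring"]] = (10, 0)        # perpendicular to (0,-10)
        frames[:, FINGER_MCP["little"]] = (1, 1)
        frames[:, FINGER_TIP["little"]] = (2, 2)
        series = LandmarkSeries(60.0, frames, "hand_open")
        signals = handopen_signal(series)
        assert signals["index"].v[0] == pytest.approx(180.0)
        assert signals["ring"].v[0] == pytest.approx(90.0)

    def test_mean_is_mean_of_fingers(self):
        series = generate_landmarks("hand_open", 2.0, 50.0, fps=60, duration_s=3)
        signals = handopen_signal(series)
        stacked = np.mean([signals[f].v for f in FINGER_MCP], axis=0)
        assert np.allclose(signals["mean"].v, stacked)


class TestCycleDetection:
    def test_sinusoid_cycle_count(self):
        cycles = detect_cycles(_sine_signal(freq=2.0, duration=10.0))
        assert 19 <= len(cycles) <= 20

    def test_constant_signal_no_cycles(self):
        t = np.arange(300) / 60
        sig = KinematicSignal(t, np.full(300, 0.7), "finger_tap", "tap_distance")
        assert detect_cycles(sig) == []

    def test_noise_robust_count(self):
        clean = detect_cycles(_sine_signal(freq=2.0))
        noisy = detect_cycles(_sine_signal(freq=2.0, noise=0.2, seed=5))
        assert len(noisy) == len(clean)

    def test_short_signal_rejected(self):
        sig = _sine_signal(duration=1.0)
        with pytest.raises(ValueError, match="2 s"):
            detect_cycles(sig)


class TestFeatures:
    def test_analytic_sinusoid(self):
        feats = extract_features(_sine_signal(freq=2.32, duration=10.0))
        assert feats.frequency == pytest.approx(2.32, abs=0.05)
        assert feats.amplitude == pytest.approx(0.8, abs=0.05)
        assert abs(feats.amplitude_decay) < 0.01
        assert abs(feats.velocity_decay) < 0.02

    def test_decay_closed_form(self):
        # per-cycle excursions 1.0, 0.9, 0.8, 0.7 -> slope/first = -0.10
        fps, freq = 200.0, 1.0
        t = np.arange(int(4 * fps)) / fps
        amp = 1.0 - 0.1 * np.floor(freq * t)
        v = amp * (0.5 - 0.5 * np.cos(2 * np.pi * freq * t))
        feats = extract_features(KinematicSignal(t, v, "finger_tap", "tap_distance"))
        assert feats.amplitude_decay == pytest.approx(-0.10, abs=0.01)

    def test_time_reversal_flips_decay_sign(self):
        fps, freq = 200.0, 2.0
        t = np.arange(int(8 * fps)) / fps
        amp = 1.0 - 0.08 * np.floor(freq * t)
        v = amp * (0.5 - 0.5 * np.cos(2 * np.pi * freq * t))
        fwd = extract_features(KinematicSignal(t, v, "finger_tap", "tap_distance"))
        rev = extract_features(KinematicSignal(t, v[::-1], "finger_tap", "tap_distance"))
        assert fwd.amplitude_decay < 0 < rev.amplitude_decay

    def test_too_few_cycles_leaves_decay_unset(self):
        feats = extract_features(_sine_signal(freq=0.4, duration=5.0))
        assert feats.n_cycles < 3
        assert feats.amplitude_decay is None


class TestRoundTrip:
    """Generator -> landmark series -> features parameter recovery."""

    @pytest.mark.parametrize("freq,amp,decay,duration", [
        (2.32, 0.8, 0.0, 10.0), (2.0, 0.6, 0.10, 4.0),
        (3.0, 0.9, 0.05, 5.0), (1.5, 0.5, 0.0, 10.0),
    ])
    def test_tap_parameter_recovery(self, freq, amp, decay, duration):
        # durations keep the decaying envelope positive across the recording
        series = generate_landmarks("finger_tap", freq, amp, decay_per_cycle=decay,
                                    noise_sd=0.5, fps=60, duration_s=duration, seed=3)
        feats = extract_features(fingertap_signal(series))
        assert feats.frequency == pytest.approx(freq, rel=0.05)
        if decay == 0.0:
            assert feats.amplitude == pytest.approx(amp, rel=0.05)
        else:
            assert feats.amplitude_decay == pytest.approx(-decay, abs=0.02)

    def test_open_frequency_recovery(self):
        series = generate_landmarks("hand_open", 1.94, 60.0, fps=60, duration_s=10)
        feats = extract_features(handopen_signal(series)["mean"])
        assert feats.frequency == pytest.approx(1.94, rel=0.05)
        assert feats.amplitude == pytest.approx(60.0, rel=0.1)

    def test_feature_scale_invariance(self):
        series = generate_landmarks("finger_tap", 2.32, 0.8, fps=60, duration_s=10)
        scaled = LandmarkSeries(series.fps, series.frames * 3.0, series.task)
        f1 = extract_features(fingertap_signal(series))
        f2 = extract_features(fingertap_signal(scaled))
        assert f1.frequency == pytest.approx(f2.frequency)
        assert f1.amplitude == pytest.approx(f2.amplitude)
        assert f1.speed == pytest.approx(f2.speed)

    def test_frame_rate_robustness(self):
        hi = generate_landmarks("finger_tap", 2.32, 0.8, fps=60, duration_s=10)
        lo = generate_landmarks("finger_tap", 2.32, 0.8, fps=30, duration_s=10)
        f_hi = extract_features(fingertap_signal(hi)).frequency
        f_lo = extract_features(fingertap_signal(lo)).frequency
        assert abs(f_hi - f_lo) / f_hi < 0.02

    def test_severity_sweep_monotone(self):
        levels = np.linspace(0, 1, 8)
        freqs, speeds = [], []
        for i, s in enumerate(levels):
            series = landmarks_for_severity(s, seed=100 + i)
            feats = extract_features(fingertap_signal(series))
            freqs.append(feats.frequency)
            speeds.append(feats.speed)
        assert scipy.stats.spearmanr(levels, freqs).statistic < 0
        assert scipy.stats.spearmanr(levels, speeds).statistic < 0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_landmarks("finger_tap", 20.0, 0.8, fps=30)
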