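import numpy as np
import pytest
from scipy import stats as sps

from demgaze.events import (
    DetectionConfig,
    SaccadeEvent,
    classify_axis,
    detect_saccades,
    estimate_noise_thresholds,
    parse_fixations,
)
from demgaze.preprocess import RawGazeStream, kinematics, lowpass_zero_phase, resample_uniform
from demgaze.simulate import NoiseModel, ReaderProfile, simulate_trial
from demgaze.geometry import build_layout


def _noise_signal(seed=0, n=5000, sd=0.03):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 500.0
    stream = RawGazeStream(
        t=t, x=rng.normal(0, sd, n), y=rng.normal(0, sd, n), valid=np.ones(n, bool)
    )
    return kinematics(lowpass_zero_phase(resample_uniform(stream)))


def _step_signal(steps, fix_ms=250, amp=3.0, sd=0.02, seed=1, fix_ms_list=None):
    """Horizontal staircase: `steps` jumps of `amp` deg with raised-cosine profiles."""
    rng = np.random.default_rng(seed)
    fs = 500.0
    durations = fix_ms_list if fix_ms_list is not None else [fix_ms] * steps
    sac_n = int(0.030 * fs)
    x = []
    level = 0.0
    onsets = []
    for d in durations:
        x.extend([level] * int(d / 1000 * fs))
        onsets.append(len(x) / fs)
        u = np.arange(1, sac_n + 1) / sac_n
        x.extend(level + amp * (u - np.sin(2 * np.pi * u) / (2 * np.pi)))
        level += amp
    x.extend([level] * int(durations[-1] / 1000 * fs))
    x = np.asarray(x) + rng.normal(0, sd, len(x))
    t = np.arange(len(x)) / fs
    stream = RawGazeStream(t=t, x=x, y=rng.normal(0, sd, len(x)), valid=np.ones(len(x), bool))
    return kinematics(lowpass_zero_phase(resample_uniform(stream))), onsets


class TestThresholds:
    def test_two_pass_on_pure_noise(self):
        sig = _noise_signal()
        cfg = DetectionConfig(velocity_floor=0.0, velocity_ceiling=1e9)
        v_thr, a_thr = estimate_noise_thresholds(sig, cfg)
        # matches the documented two-pass computation exactly
        v1 = 3 * np.median(np.abs(np.abs(sig.v) - np.median(np.abs(sig.v))))
        noise = np.abs(sig.v)[np.abs(sig.v) < v1]
        assert v_thr == pytest.approx(3 * np.median(np.abs(noise - np.median(noise))))
        # truncating at the provisional threshold shrinks the estimate, but
        # it stays the same order of magnitude and does not collapse
        assert 0.3 * v1 <= v_thr <= v1

    def test_threshold_within_configured_bounds(self, errorless_trial):
        cfg = DetectionConfig()
        v_thr, a_thr = estimate_noise_thresholds(errorless_trial["sig"], cfg)
        assert cfg.velocity_floor <= v_thr <= cfg.velocity_ceiling
        assert a_thr > 0

    def test_degenerate_constant_signal_floored(self):
        t = np.arange(1000) / 500.0
        stream = RawGazeStream(t=t, x=np.zeros(1000), y=np.zeros(1000), valid=np.ones(1000, bool))
        sig = kinematics(resample_uniform(stream))
        v_thr, _ = estimate_noise_thresholds(sig, DetectionConfig())
        assert v_thr == DetectionConfig().velocity_floor


class TestClassifyAxis:
    @pytest.mark.parametrize(
        "dx,dy,expected",
        [
            (1.0, 0.5, "horizontal"),  # ~27 deg
            (-2.0, 0.3, "horizontal"),  # near 180
            (0.5, 1.0, "vertical"),  # ~63 deg
            (1.0, 1.0, "vertical"),  # exactly 45: 'below' is strict
            (0.0, -1.0, "vertical"),
        ],
    )
    def test_rule(self, dx, dy, expected):
        s = SaccadeEvent(onset=0, offset=0.03, dx=dx, dy=dy, peak_velocity=100)
        assert classify_axis(s) == expected

    def test_zero_displacement_rejected(self):
        s = SaccadeEvent(onset=0, offset=0.03, dx=0.0, dy=0.0, peak_velocity=0)
        with pytest.raises(ValueError):
            classify_axis(s)


class TestDetectSaccades:
    def test_staircase_all_found(self):
        sig, onsets = _step_signal(steps=10)
        events = detect_saccades(sig, DetectionConfig())
        assert len(events) == 10
        # the zero-phase 40 Hz low-pass spreads each velocity profile by a few
        # samples in both directions, bounding achievable timing accuracy
        for t_on, ev in zip(onsets, events):
            assert abs(ev.onset - t_on) * 1000 <= 10.0
            assert abs(ev.offset - (t_on + 0.030)) * 1000 <= 10.0
            assert ev.amplitude == pytest.approx(3.0, abs=0.2)

    def test_noise_only_none_found(self):
        events = detect_saccades(_noise_signal(), DetectionConfig())
        assert events == []

    def test_micro_jitter_rejected_by_verification(self):
        # square-wave jitter crosses low thresholds but has no net displacement
        fs = 500.0
        n = 3000
        x = 0.02 * (-1.0) ** (np.arange(n) // 5)
        stream = RawGazeStream(t=np.arange(n) / fs, x=x, y=np.zeros(n), valid=np.ones(n, bool))
        sig = kinematics(resample_uniform(stream))
        events = detect_saccades(sig, DetectionConfig(), thresholds=(5.0, 10.0))
        assert events == []

    def test_ground_truth_recall_precision(self, errorless_trial):
        gt = errorless_trial["gt"]
        det = errorless_trial["ev"].saccades
        big = [g for g in gt.saccades if g.amplitude >= 1.0]
        used = set()
        matched = []
        for g in big:
            for i, d in enumerate(det):
                if i not in used and d.onset < g.offset and d.offset > g.onset:
                    used.add(i)
                    matched.append((g, d))
                    break
        recall = len(matched) / len(big)
        precision = len(matched) / len(det)
        assert recall >= 0.95 and precision >= 0.95
        amp_err = [abs(d.amplitude - g.amplitude) for g, d in matched]
        assert max(amp_err) <= 0.2

    def test_main_sequence_peak_velocity(self, errorless_trial):
        det = errorless_trial["ev"].saccades
        rho = sps.spearmanr([s.amplitude for s in det], [s.peak_velocity for s in det])[0]
        assert rho > 0.9

    def test_events_ordered_non_overlapping(self, errorless_trial):
        det = errorless_trial["ev"].saccades
        for a, b in zip(det, det[1:]):
            assert b.onset >= a.offset


class TestParseFixations:
    def test_single_interval(self):
        sig, _ = _step_signal(steps=2, fix_ms=400)
        cfg = DetectionConfig()
        sacc = detect_saccades(sig, cfg)
        fix = parse_fixations(sacc, sig, cfg)
        # 2 saccades -> 3 fixations (lead, between, trail)
        assert len(fix) == 3
        assert fix[1].duration_ms == pytest.approx(400, abs=15)

    def test_no_saccades_whole_segment(self):
        sig = _noise_signal(n=2500)
        fix = parse_fixations([], sig, DetectionConfig())
        assert len(fix) == 1
        assert fix[0].duration_ms == pytest.approx(2500 / 500 * 1000, abs=5)

    def test_outlier_rule_flags_blink_artifact(self):
        # 50 fixations ~200 ms plus one 1200 ms: only the long one is
        # excluded from duration statistics, its time still counts
        sig, _ = _step_signal(steps=51, fix_ms_list=[200] * 25 + [1200] + [200] * 25)
        cfg = DetectionConfig()
        sacc = detect_saccades(sig, cfg)
        fix = parse_fixations(sacc, sig, cfg)
        flagged = [f for f in fix if f.duration_outlier]
        assert len(flagged) == 1
        assert flagged[0].duration_ms == pytest.approx(1200, abs=20)
        # time conservation includes the flagged fixation
        total = sum(f.end - f.start for f in fix) + sum(s.offset - s.onset for s in sacc)
        seg = sum((e - s) / sig.fs for s, e in sig.segments)
        assert total == pytest.approx(seg, abs=1e-6)

    def test_tiling_time_conservation(self, errorless_trial):
        sig = errorless_trial["sig"]
        ev = errorless_trial["ev"]
        total_sacc = sum(s.offset - s.onset for s in ev.saccades)
        total_fix = sum(f.end - f.start for f in ev.fixations)
        seg_time = sum((e - s) / sig.fs for s, e in sig.segments)
        assert total_sacc + total_fix == pytest.approx(seg_time, abs=1e-6)
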