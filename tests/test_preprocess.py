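import numpy as np
import pytest

from demgaze.preprocess import (
    NoDataError,
    PreprocessConfig,
    RawGazeStream,
    differentiate_nr,
    kinematics,
    lowpass_zero_phase,
    median_prefilter,
    preprocess,
    resample_uniform,
    select_best_eye,
)
from demgaze.simulate import NOISELESS, ERRORLESS_PROFILE, simulate_trial
from demgaze.geometry import build_layout


def _stream(t, x, y=None, valid=None):
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.zeros_like(x) if y is None else np.asarray(y, float)
    valid = np.ones(len(t), bool) if valid is None else np.asarray(valid, bool)
    return RawGazeStream(t=t, x=x, y=y, valid=valid)


class TestSelectBestEye:
    def test_larger_valid_fraction_wins(self):
        left = _stream([0, 0.002, 0.004], [0, 0, 0], valid=[1, 1, 1])
        right = _stream([0, 0.002, 0.004], [0, 0, 0], valid=[1, 1, 0])
        assert select_best_eye(left, right) is left

    def test_tie_goes_right(self):
        left = _stream([0, 0.002], [0, 0])
        right = _stream([0, 0.002], [0, 0])
        assert select_best_eye(left, right) is right

    def test_one_empty(self):
        left = _stream([0, 0.002], [0, 0])
        assert select_best_eye(left, None) is left
        with pytest.raises(NoDataError):
            select_best_eye(None, None)


class TestMedianPrefilter:
    def test_constant_unchanged(self):
        s = _stream(np.arange(100) * 0.002, np.full(100, 3.0))
        out = median_prefilter(s)
        assert np.allclose(out.x, 3.0)

    def test_single_spike_removed(self):
        x = np.full(100, 1.0)
        x[50] = 100.0
        out = median_prefilter(_stream(np.arange(100) * 0.002, x))
        assert np.allclose(out.x, 1.0)

    def test_ramp_interior_unchanged(self):
        x = np.arange(100, dtype=float)
        out = median_prefilter(_stream(np.arange(100) * 0.002, x))
        assert np.allclose(out.x[6:-6], x[6:-6])


class TestResample:
    def test_uniform_input_reproduced(self):
        t = np.arange(200) / 500.0
        x = np.sin(2 * np.pi * 3 * t)
        sig = resample_uniform(_stream(t, x))
        assert sig.fs == 500.0
        assert np.allclose(sig.x, x, atol=1e-12)

    def test_linear_ramp_exact(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, 600))
        t = t[np.diff(t, prepend=-1) > 1e-5]
        x = 5.0 * t + 1.0
        sig = resample_uniform(_stream(t, x))
        assert np.allclose(sig.x, 5.0 * sig.t + 1.0, atol=1e-9)

    def test_long_dropout_marked_invalid(self):
        t = np.concatenate([np.arange(0, 0.5, 0.002), np.arange(0.7, 1.2, 0.002)])
        sig = resample_uniform(_stream(t, np.zeros(len(t))))
        gap = (sig.t > 0.5) & (sig.t < 0.7)
        assert not sig.valid[gap].any()
        assert len(sig.segments) == 2

    def test_too_few_valid(self):
        with pytest.raises(NoDataError):
            resample_uniform(_stream([0.0, 0.1], [0, 0], valid=[1, 0]))


class TestLowpass:
    def test_dc_invariance(self):
        t = np.arange(1000) / 500.0
        sig = resample_uniform(_stream(t, np.full(len(t), 2.5)))
        out = lowpass_zero_phase(sig)
        assert np.allclose(out.x, 2.5, atol=1e-9)

    def test_passband_preserved_zero_phase(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 5 * t)
        out = lowpass_zero_phase(resample_uniform(_stream(t, x)))
        core = slice(500, -500)
        amp = out.x[core].max()
        assert amp == pytest.approx(1.0, rel=0.01)
        # zero phase: cross-correlation peak at zero lag (< 0.5 ms shift)
        lags = np.arange(-5, 6)
        cc = [np.dot(out.x[core], np.roll(x, k)[core]) for k in lags]
        assert abs(lags[int(np.argmax(cc))]) * 2.0 < 0.5  # ms

    def test_cutoff_minus_six_db(self):
        t = np.arange(5000) / 500.0
        x = np.sin(2 * np.pi * 40 * t)
        out = lowpass_zero_phase(resample_uniform(_stream(t, x)))
        amp = np.abs(out.x[1000:-1000]).max()
        assert amp == pytest.approx(0.5, rel=0.05)  # -3 dB per pass, two passes


class TestDifferentiator:
    def test_constant_zero(self):
        assert np.allclose(differentiate_nr(np.full(50, 7.0), 500.0), 0.0)

    def test_ramp_exact_interior(self):
        x = 3.0 * np.arange(100) / 500.0
        d = differentiate_nr(x, 500.0)
        assert np.allclose(d[4:-4], 3.0, atol=1e-9)

    def test_quadratic_exact_interior(self):
        t = np.arange(100) / 500.0
        d = differentiate_nr(t**2, 500.0)
        assert np.allclose(d[4:-4], 2 * t[4:-4], atol=1e-9)

    def test_noise_suppression_vs_central_difference(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1.0, 100_000)
        nr = differentiate_nr(x, 500.0)[4:-4]
        central = np.gradient(x) * 500.0
        assert nr.std() < central[4:-4].std()


class TestKinematics:
    def test_track_velocity_vector_sum(self):
        t = np.arange(500) / 500.0
        sig = resample_uniform(_stream(t, 3.0 * t, 4.0 * t))
        out = kinematics(sig)
        assert np.allclose(out.v[10:-10], 5.0, atol=1e-6)
        assert np.all(out.v >= 0)
        assert np.allclose(out.v, np.hypot(out.vx, out.vy))

    def test_pure_horizontal(self):
        t = np.arange(500) / 500.0
        out = kinematics(resample_uniform(_stream(t, 2.0 * t, np.zeros(len(t)))))
        assert np.allclose(out.v[10:-10], np.abs(out.vx[10:-10]))

    def test_fixation_noise_velocity_scale(self):
        rng = np.random.default_rng(3)
        t = np.arange(2500) / 500.0
        x = rng.normal(0, 0.03, len(t))
        y = rng.normal(0, 0.03, len(t))
        sig = kinematics(lowpass_zero_phase(resample_uniform(_stream(t, x, y))))
        assert np.median(sig.v) < 20.0  # comfortably under the typical threshold


class TestFullChain:
    def test_saccade_endpoints_preserved(self):
        # a noiseless synthetic saccade passes the whole chain with its
        # start/end positions intact to better than 0.05 deg
        layout = build_layout("C")
        stream, gt = simulate_trial(ERRORLESS_PROFILE, layout, NOISELESS, seed=0)
        sig = preprocess(stream)
        s = gt.saccades[10]
        i0 = sig.index_of(s.onset - 0.01)
        i1 = sig.index_of(s.offset + 0.01)
        assert sig.x[i0] == pytest.approx(s.x0, abs=0.05)
        assert sig.x[i1] == pytest.approx(s.x1, abs=0.05)

    def test_deterministic(self):
        layout = build_layout("C")
        s1, _ = simulate_trial(ERRORLESS_PROFILE, layout, seed=5)
        a = preprocess(s1)
        b = preprocess(s1)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.v, b.v)
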