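import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosense import (NoiseConfig, correct_baseline, estimate_baseline,
                         generate_record, moving_average, notch_50hz)

FS = 500.0


def fit_sine_amplitude(x, fs, freq):
    """Least-squares amplitude of a sinusoid at a known frequency."""
    t = np.arange(len(x)) / fs
    basis = np.column_stack([np.sin(2 * np.pi * freq * t),
                             np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return float(np.hypot(*coef))


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(50, 3.3), 7),
                                   np.full(50, 3.3))

    def test_window_one_is_identity(self, rng):
        x = rng.standard_normal(40)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_interior_matches_direct_mean(self):
        x = np.array([1.0, 2, 3, 4, 5])
        out = moving_average(x, 3)
        # independent oracle: mean of each centred triple
        np.testing.assert_allclose(out[1:4], [2.0, 3.0, 4.0])

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 0)
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 11)


class TestBaselineEstimate:
    def test_zero_input_gives_zero_baseline(self):
        assert np.all(estimate_baseline(np.zeros(1000), FS) == 0)

    def test_slow_ramp_recovered(self):
        n = 2000
        ramp = np.linspace(0, 1.0, n)
        est = estimate_baseline(ramp, FS)
        interior = slice(200, n - 200)
        assert np.max(np.abs(est[interior] - ramp[interior])) < 0.01

    def test_narrow_spike_suppressed(self):
        x = np.zeros(1000)
        x[500:506] = 5.0  # 12 ms spike
        assert np.max(np.abs(estimate_baseline(x, FS))) < 1e-9

    def test_too_short_record_raises(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.zeros(100), FS)


class TestBaselineCorrection:
    def test_additive_constant_invariance(self, rng):
        x = rng.standard_normal(2000) * 0.2
        a = correct_baseline(x, FS)
        b = correct_baseline(x + 0.7, FS)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_drift_reduced_by_90_percent(self):
        rec = generate_record("NORMAL", 20, noise=NoiseConfig(
            baseline_amp=0.5, baseline_freq=0.3, powerline_amp=0,
            emg_sigma=0, seed=1))
        before = fit_sine_amplitude(rec.samples, FS, 0.3)
        after = fit_sine_amplitude(correct_baseline(rec.samples, FS), FS, 0.3)
        assert after <= 0.1 * before

    def test_isoelectric_segments_near_zero_after_correction(self):
        rec = generate_record("NORMAL", 20, noise=NoiseConfig(
            baseline_amp=0.3, powerline_amp=0, emg_sigma=0, seed=2))
        x = correct_baseline(rec.samples, FS)
        # TP segments: 420..480 ms after each annotated R centre
        for ann in rec.annotations[1:-1]:
            seg = x[ann.sample_index + 210:ann.sample_index + 240]
            assert np.max(np.abs(seg)) < 0.05

    def test_second_baseline_subtraction_changes_rms_below_1_percent(self):
        """Idempotence of the correction: subtracting a freshly estimated
        baseline from an already-corrected signal moves its RMS by far
        less than 1% (what little the cascade still finds is a small,
        nearly orthogonal component)."""
        rec = generate_record("NORMAL", 20, noise=NoiseConfig(
            baseline_amp=0.3, seed=3))
        once = correct_baseline(rec.samples, FS)
        again = once - estimate_baseline(once, FS)
        rms_once = np.sqrt(np.mean(once ** 2))
        rms_again = np.sqrt(np.mean(again ** 2))
        assert abs(rms_again - rms_once) < 0.01 * rms_once


class TestNotch:
    def test_50hz_tone_attenuated(self):
        t = np.arange(5000) / FS
        tone = np.sin(2 * np.pi * 50 * t)
        out = notch_50hz(tone, FS)
        assert np.sqrt(np.mean(out ** 2)) <= 0.1 * np.sqrt(np.mean(tone ** 2))

    def test_10hz_tone_passes(self):
        t = np.arange(5000) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        out = notch_50hz(tone, FS)
        assert np.sqrt(np.mean(out ** 2)) >= 0.89 * np.sqrt(np.mean(tone ** 2))

    def test_zero_in_zero_out(self):
        assert np.all(notch_50hz(np.zeros(1000), FS) == 0)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError):
            notch_50hz(np.zeros(1000), 80.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=400, max_value=2000), st.integers(0, 2 ** 31 - 1))
def test_filters_preserve_length_and_finiteness(n, seed):
    x = np.random.default_rng(seed).standard_normal(n)
    for fn in (lambda v: moving_average(v, 9),
               lambda v: correct_baseline(v, FS),
               lambda v: notch_50hz(v, FS)):
        out = fn(x)
        assert len(out) == n and np.all(np.isfinite(out))
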