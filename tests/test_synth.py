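import numpy as np
import pytest

from cardiosense import (ADCConfig, BeatMorphology, NoiseConfig, PowerBudget,
                         WaveParams, battery_life, dequantize_adc,
                         generate_beat, generate_record, morphology_for,
                         quantize_adc, required_capacity)
from cardiosense.synth import beat_r_offset, st_plateau_span_ms

FS = 500.0


class TestGenerateBeat:
    def test_zero_amplitudes_give_zero_beat(self):
        flat = BeatMorphology(
            p=WaveParams(0, 25, -180), q=WaveParams(0, 10, -25),
            r=WaveParams(0, 12, 0), s=WaveParams(0, 10, 25),
            t=WaveParams(0, 60, 300))
        beat = generate_beat(flat, FS, 1000)
        np.testing.assert_array_equal(beat, np.zeros(500))

    def test_r_peak_amplitude_and_position(self):
        beat = generate_beat(BeatMorphology(), FS, 1000)
        assert len(beat) == 500
        assert np.argmax(beat) == beat_r_offset(FS, 1000) == 250
        assert beat.max() == pytest.approx(1.0, abs=0.01)

    def test_st_plateau_mean_matches_offset(self):
        morph = morphology_for("ST_ELEVATION", st_offset_mv=0.2)
        base = morphology_for("NORMAL")
        elev = generate_beat(morph, FS, 1000)
        norm = generate_beat(base, FS, 1000)
        lo_ms, hi_ms = st_plateau_span_ms(morph)
        center = beat_r_offset(FS, 1000)
        lo = center + int(lo_ms * FS / 1000)
        hi = center + int(hi_ms * FS / 1000)
        assert np.mean(elev[lo:hi] - norm[lo:hi]) == pytest.approx(0.2, abs=0.02)

    def test_t_sign_flips_t_wave(self):
        inv = generate_beat(morphology_for("T_INVERSION"), FS, 1000)
        center = beat_r_offset(FS, 1000)
        t_idx = center + int(0.300 * FS)
        assert inv[t_idx] == pytest.approx(-0.3, abs=0.02)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            generate_beat(BeatMorphology(), 0, 1000)
        with pytest.raises(ValueError):
            generate_beat(BeatMorphology(), FS, 100)  # shorter than offsets


class TestGenerateRecord:
    def test_ten_beats_at_60bpm_is_5000_samples(self):
        rec = generate_record("NORMAL", 10, fs=FS, mean_bpm=60.0)
        assert rec.n_samples == 5000
        assert len(rec.annotations) == 10

    def test_same_seed_is_bitwise_identical(self):
        a = generate_record("NORMAL", 10, noise=NoiseConfig(seed=7), rr_jitter=0.05)
        b = generate_record("NORMAL", 10, noise=NoiseConfig(seed=7), rr_jitter=0.05)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert [x.sample_index for x in a.annotations] == \
               [x.sample_index for x in b.annotations]

    def test_different_seed_differs(self):
        a = generate_record("NORMAL", 10, noise=NoiseConfig(seed=7))
        b = generate_record("NORMAL", 10, noise=NoiseConfig(seed=8))
        assert not np.array_equal(a.samples, b.samples)

    def test_adc_roundtrip_error_bounded_by_one_step(self):
        adc = ADCConfig()
        rec = generate_record("NORMAL", 5, noise=NoiseConfig(
            baseline_amp=0, powerline_amp=0, emg_sigma=0), adc=adc)
        clean = generate_record("NORMAL", 5, noise=NoiseConfig(
            baseline_amp=0, powerline_amp=0, emg_sigma=0))
        assert np.max(np.abs(rec.samples - clean.samples)) <= adc.step_mv

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError):
            generate_record("SINUS", 5)


class TestADC:
    def test_10bit_3v_step_is_2p93_mv(self):
        assert ADCConfig(bits=10, vref=3.0).step_mv == pytest.approx(2.93, abs=0.005)

    def test_unipolar_code_boundaries(self):
        adc = ADCConfig()
        assert quantize_adc(np.array([0.0]), adc, bipolar=False)[0] == 0
        assert quantize_adc(np.array([3.0 - 1e-9]), adc, bipolar=False)[0] == 1023

    def test_bipolar_midrail_mapping(self):
        adc = ADCConfig()
        assert quantize_adc(np.array([-1.5]), adc)[0] == 0
        assert quantize_adc(np.array([0.0]), adc)[0] == 512
        assert quantize_adc(np.array([10.0]), adc)[0] == 1023  # clipped

    def test_quantize_dequantize_error_below_one_step(self, rng):
        adc = ADCConfig()
        v = rng.uniform(-1.4, 1.4, size=200)
        back = dequantize_adc(quantize_adc(v, adc), adc)
        assert np.max(np.abs(back - v)) <= adc.step_v


class TestPowerModel:
    def test_battery_life_1000mah_9p3ma(self):
        hours = battery_life(PowerBudget(1000, 9.3, 0.70))
        assert hours == pytest.approx(75.27, abs=0.01)
        assert round(hours) == 75

    def test_capacity_for_24h(self):
        mah = required_capacity(24, 9.3, 0.70)
        assert mah == pytest.approx(318.9, abs=0.1)
        assert round(mah / 10) * 10 == 320

    def test_linearity_and_inverse(self):
        h1 = battery_life(PowerBudget(500, 9.3))
        h2 = battery_life(PowerBudget(1000, 9.3))
        assert h2 == pytest.approx(2 * h1)
        assert battery_life(PowerBudget(required_capacity(24, 9.3, 0.7), 9.3, 0.7)) \
            == pytest.approx(24)

    def test_zero_capacity_and_zero_load(self):
        assert battery_life(PowerBudget(0, 9.3)) == 0
        with pytest.raises(ValueError):
            battery_life(PowerBudget(1000, 0))
        with pytest.raises(ValueError):
            required_capacity(24, 9.3, 0)
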