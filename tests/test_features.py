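import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosense import (FeatureScore, embd, extract_features, f_features,
                         feature_auc, folded_auc, joint_tf_features,
                         screen_features, select_features, t_features, wvd)

FS = 500.0


def direct_moments(x):
    """Independent direct-summation oracle for the five statistics."""
    n = len(x)
    m = sum(x) / n
    var = sum((v - m) ** 2 for v in x) / n
    sd = math.sqrt(var)
    skew = sum((v - m) ** 3 for v in x) / (n * sd ** 3)
    kurt = sum((v - m) ** 4 for v in x) / (n * sd ** 4)
    return m, var, skew, kurt, sd / m


class TestTimeFeatures:
    def test_worked_example(self):
        f = t_features([1.0, 2.0, 3.0, 4.0])
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["kurtosis"] == pytest.approx(1.64)
        assert f["coeff_variation"] == pytest.approx(0.4472, abs=1e-4)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(50) + 3.0
            f = t_features(x)
            m, var, skew, kurt, cv = direct_moments(list(x))
            assert f["mean"] == pytest.approx(m, abs=1e-12)
            assert f["variance"] == pytest.approx(var, abs=1e-12)
            assert f["skewness"] == pytest.approx(skew, abs=1e-10)
            assert f["kurtosis"] == pytest.approx(kurt, abs=1e-10)
            assert f["coeff_variation"] == pytest.approx(cv, abs=1e-12)

    def test_constant_sequence_gives_nan_sentinels(self):
        f = t_features(np.full(10, 2.0))
        assert f["variance"] == 0.0
        assert all(np.isnan(f[k]) for k in ("skewness", "kurtosis",
                                            "coeff_variation"))

    def test_symmetric_sequence_has_zero_skewness(self, rng):
        x = rng.standard_normal(30)
        sym = np.concatenate([x, 2 * x.mean() - x])  # mirror about the mean
        assert t_features(sym)["skewness"] == pytest.approx(0.0, abs=1e-10)


class TestSpectralFeatures:
    def test_impulse_is_spectrally_flat(self):
        x = np.zeros(64)
        x[0] = 1.0
        f = f_features(x, FS)
        assert f["spectral_flatness"] == pytest.approx(1.0, abs=1e-9)
        assert f["spectral_entropy"] == pytest.approx(1.0, abs=1e-9)

    def test_single_tone_concentrates_spectrum(self):
        t = np.arange(256) / FS
        f = f_features(np.sin(2 * np.pi * 62.5 * t), FS)
        assert f["spectral_entropy"] < 0.2
        assert f["spectral_flatness"] < 0.05

    def test_flux_zero_for_stationary_tone_positive_for_am(self):
        t = np.arange(512) / FS
        tone = np.sin(2 * np.pi * 62.5 * t)
        am = (1 + 0.8 * np.sin(2 * np.pi * 3 * t)) * tone
        f_tone = f_features(tone, FS)["spectral_flux"]
        f_am = f_features(am, FS)["spectral_flux"]
        assert f_tone < 1e-6
        assert f_am > 100 * max(f_tone, 1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            f_features(np.zeros(4), FS)


class TestJointFeatures:
    def test_scaling_leaves_entropy_flatness_invariant(self, rng):
        x = rng.standard_normal(96)
        a = joint_tf_features(wvd(x, FS))
        b = joint_tf_features(wvd(5.0 * x, FS))
        assert b["tf_spectral_entropy"] == pytest.approx(a["tf_spectral_entropy"], rel=1e-9)
        assert b["tf_spectral_flatness"] == pytest.approx(a["tf_spectral_flatness"], rel=1e-9)

    def test_moments_covariant_with_square_of_scale(self, rng):
        x = rng.standard_normal(96)
        a = joint_tf_features(embd(x, FS))
        b = joint_tf_features(embd(2.0 * x, FS))
        assert b["tf_mean"] == pytest.approx(4.0 * a["tf_mean"], rel=1e-6)
        assert b["tf_variance"] == pytest.approx(16.0 * a["tf_variance"], rel=1e-6)
        assert b["tf_kurtosis"] == pytest.approx(a["tf_kurtosis"], rel=1e-6)

    def test_two_tone_spreads_mass_more_than_one_tone(self):
        t = np.arange(256) / FS
        one = np.sin(2 * np.pi * 60 * t)
        two = (np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 120 * t)) / np.sqrt(2)
        f1 = joint_tf_features(wvd(one, FS))
        f2 = joint_tf_features(wvd(two, FS))
        assert f2["tf_variance"] < f1["tf_variance"]  # same energy over more cells

    def test_all_zero_tfd_raises(self):
        M = wvd(np.ones(32) * 0 + 1e-30, FS)
        M.values[:] = 0.0
        with pytest.raises(ValueError):
            joint_tf_features(M)

    def test_full_vector_has_16_named_features(self, rng):
        f = extract_features(rng.standard_normal(64), FS, "spec")
        assert len(f) == 16


class TestAUC:
    def brute_force(self, pos, neg):
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        return wins / (len(pos) * len(neg))

    def test_worked_example(self):
        assert feature_auc([0.8, 0.4], [0.6, 0.2]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert feature_auc([2.0, 3.0], [0.0, 1.0]) == 1.0

    def test_all_ties_is_half(self):
        assert feature_auc([1.0, 1.0], [1.0, 1.0]) == 0.5

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 2 ** 31 - 1))
    def test_matches_pairwise_concordance(self, n1, n2, seed):
        r = np.random.default_rng(seed)
        pos = np.round(r.standard_normal(n1), 1)  # rounding forces ties
        neg = np.round(r.standard_normal(n2), 1)
        assert feature_auc(pos, neg) == pytest.approx(
            self.brute_force(pos, neg), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            feature_auc([], [1.0])


class TestScreening:
    def _score(self, auc, selected=None):
        fold = folded_auc(auc)
        return FeatureScore("f", auc, fold, fold >= 0.5)

    def test_threshold_is_inclusive_at_0_5(self):
        report = [self._score(0.50)]
        assert select_features(report) == ["f"]

    def test_folded_below_half_never_happens(self):
        assert folded_auc(0.49) == 0.51  # folding reflects anti-correlation

    def test_raw_auc_below_threshold_excluded(self):
        report = [FeatureScore("f", 0.49, 0.49, False)]
        assert select_features(report, min_auc=0.5) == []

    def test_empty_report_raises(self):
        with pytest.raises(ValueError):
            select_features([])

    def test_screen_features_end_to_end(self, rng):
        import pandas as pd
        pos = rng.normal(1.0, 0.2, size=(40, 1))
        neg = rng.normal(0.0, 0.2, size=(40, 1))
        table = pd.DataFrame(np.vstack([pos, neg]), columns=["sep"])
        table["junk"] = rng.standard_normal(80)
        labels = np.array(["A"] * 40 + ["B"] * 40)
        report = screen_features(table, labels, positive_label="A")
        by_name = {r.feature: r for r in report}
        assert by_name["sep"].auc > 0.95 and by_name["sep"].selected
        assert by_name["junk"].auc_folded < 0.7
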