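import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosense import (ConfusionMatrix, ModelSpec, cross_validate, f_score,
                         metrics, train_model)


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionMatrix(tp=9, fn=1, tn=8, fp=2))
        assert m.recall == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.fpr == pytest.approx(0.2)
        assert m.precision == pytest.approx(0.8182, abs=1e-4)
        assert m.accuracy == pytest.approx(0.85)
        assert m.f_score == pytest.approx(0.8571, abs=1e-4)

    def test_f_score_of_reported_recall_precision(self):
        # high-recall/high-precision regime typical of a well-tuned detector
        assert round(100 * f_score(0.991, 0.983), 1) == 98.7

    def test_zero_denominator_gives_nan_sentinel_only_there(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m.recall)
        assert m.specificity == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(0.5)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 100), st.integers(1, 100),
           st.integers(1, 100), st.integers(1, 100))
    def test_metric_identities(self, tp, fp, tn, fn):
        m = metrics(ConfusionMatrix(tp, fp, tn, fn))
        assert m.fpr == pytest.approx(1.0 - m.specificity)
        assert m.f_score == pytest.approx(
            2 * m.recall * m.precision / (m.recall + m.precision))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))


def separable_toy(rng, n=40):
    X = np.vstack([rng.normal(-2, 0.3, size=(n, 2)),
                   rng.normal(+2, 0.3, size=(n, 2))])
    y = np.array(["neg"] * n + ["pos"] * n)
    return X, y


class TestTrainModel:
    @pytest.mark.parametrize("kind", ["svm_poly3", "knn"])
    def test_separable_toy_is_learned_perfectly(self, kind, rng):
        X, y = separable_toy(rng)
        model = train_model(X, y, ModelSpec(kind=kind), seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_same_seed_identical_predictions(self, rng):
        X, y = separable_toy(rng)
        probe = rng.normal(0, 2, size=(50, 2))
        a = train_model(X, y, seed=3).predict(probe)
        b = train_model(X, y, seed=3).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            train_model(X, np.array(["a"] * 10))

    def test_standardization_uses_training_statistics_only(self, rng):
        """No leakage: the fitted scaler's statistics equal the training
        set's, and are untouched by whatever is later predicted."""
        X, y = separable_toy(rng)
        model = train_model(X, y, seed=0)
        np.testing.assert_allclose(model.named_steps["scale"].mean_,
                                   X.mean(axis=0))
        model.predict(X + 100.0)  # shifted "test" data
        np.testing.assert_allclose(model.named_steps["scale"].mean_,
                                   X.mean(axis=0))


class TestCrossValidation:
    def test_folds_are_an_exact_partition(self, rng):
        X, y = separable_toy(rng, n=33)
        res = cross_validate(X, y, k=5, seed=1, positive_label="pos")
        assert res.k == 5
        assert sorted(np.unique(res.fold_assignment)) == [0, 1, 2, 3, 4]
        assert len(res.fold_assignment) == len(y)  # every sample exactly once

    def test_mean_and_std_match_direct_arithmetic(self, rng):
        X, y = separable_toy(rng, n=25)
        res = cross_validate(X, y, k=5, seed=2, positive_label="pos")
        accs = [m.accuracy for m in res.fold_metrics]
        assert res.mean()["accuracy"] == pytest.approx(np.mean(accs))
        assert res.std()["accuracy"] == pytest.approx(np.std(accs, ddof=1))

    def test_leave_one_out_boundary(self, rng):
        X, y = separable_toy(rng, n=4)
        res = cross_validate(X, y, k=len(y), seed=0, positive_label="pos")
        assert res.k == len(y)
        counts = np.bincount(res.fold_assignment)
        assert np.all(counts == 1)

    def test_stratification_keeps_both_classes_in_training(self, rng):
        X, y = separable_toy(rng, n=6)
        res = cross_validate(X, y, k=3, seed=0, positive_label="pos")
        for fold in range(3):
            train_y = y[res.fold_assignment != fold]
            assert set(train_y) == {"neg", "pos"}

    def test_too_few_samples_raise(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError):
            cross_validate(X, np.array(["a", "b", "a"]), k=5)


def test_run_tasks_requires_all_three_classes():
    from cardiosense import BeatLabel, run_tasks
    from cardiosense.segment import BeatSegment, LabeledDataset
    segs = [BeatSegment(np.zeros(50), BeatLabel.NORMAL, "s", i) for i in range(10)]
    ds = LabeledDataset(segments=segs, trace_len=50)
    with pytest.raises(ValueError):
        run_tasks(ds, 500.0)
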