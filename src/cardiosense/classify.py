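"""Binary MI classifiers (polynomial-kernel SVM, KNN), stratified
five-fold cross-validation and confusion-matrix metrics.

Two binary tasks mirror the clinical split: STEMI detection (normal vs
ST-elevation beats) and NSTEMI detection (normal vs T-inversion beats).
Features are standardized inside each training fold only — test folds are
transformed with training-fold statistics, so no information leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .records import BeatLabel
from .segment import LabeledDataset

NAN = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    """Recall (sensitivity), specificity, false-positive rate, precision,
    F-score and accuracy, all as fractions; a metric with a zero
    denominator is NaN."""

    recall: float
    specificity: float
    fpr: float
    precision: float
    f_score: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "recall": self.recall, "specificity": self.specificity,
            "fpr": self.fpr, "precision": self.precision,
            "f_score": self.f_score, "accuracy": self.accuracy,
        }


def f_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision."""
    if recall + precision == 0:
        return NAN
    return 2.0 * recall * precision / (recall + precision)


def metrics(cm: ConfusionMatrix) -> EvalMetrics:
    """Standard derived statistics of a binary confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else NAN
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else NAN
    fpr = 1.0 - spec if not np.isnan(spec) else NAN
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else NAN
    fsc = f_score(recall, precision) if not (np.isnan(recall) or np.isnan(precision)) else NAN
    acc = (cm.tp + cm.tn) / cm.total
    return EvalMetrics(recall=recall, specificity=spec, fpr=fpr,
                       precision=precision, f_score=fsc, accuracy=acc)


@dataclass(frozen=True)
class ModelSpec:
    """kind 'svm_poly3' (3rd-degree polynomial SVM, C regularization) or
    'knn' (k nearest neighbours, Euclidean). Features are standardized in
    both cases."""

    kind: str = "svm_poly3"
    svm_c: float = 1.0
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("svm_poly3", "knn"):
            raise ValueError("kind must be 'svm_poly3' or 'knn'")


def _build(spec: ModelSpec, seed: int) -> Pipeline:
    if spec.kind == "svm_poly3":
        clf = SVC(kernel="poly", degree=3, C=spec.svm_c, random_state=seed)
    else:
        clf = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_model(features: np.ndarray, labels: np.ndarray,
                spec: ModelSpec | None = None, seed: int = 0) -> Pipeline:
    """Fit a binary model; raises on single-class input."""
    spec = spec or ModelSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain two classes")
    model = _build(spec, seed)
    model.fit(X, y)
    return model


@dataclass
class CVResult:
    fold_metrics: list[EvalMetrics]
    fold_assignment: np.ndarray  # fold index per sample
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.fold_metrics)

    def mean(self) -> dict[str, float]:
        table = pd.DataFrame([m.as_dict() for m in self.fold_metrics])
        return table.mean().to_dict()

    def std(self) -> dict[str, float]:
        table = pd.DataFrame([m.as_dict() for m in self.fold_metrics])
        return table.std(ddof=1).to_dict()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean(), "std": self.std()})


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; every sample appears in exactly
    one test fold."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    counter = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for sample in idx:  # round-robin keeps folds equal-sized and
            assignment[sample] = counter % k  # each class spread across folds
            counter += 1
    return assignment


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   spec: ModelSpec | None = None, k: int = 5,
                   seed: int = 0, positive_label=None) -> CVResult:
    """Stratified k-fold cross-validation with per-fold confusion metrics.

    ``positive_label`` names the class counted as positive (defaults to
    the lexicographically last label, which puts the abnormal class on
    the positive side for the beat-label vocabulary used here).
    """
    spec = spec or ModelSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if counts.min() < 1 or len(y) < k:
        raise ValueError("too few samples for the requested folds")
    if positive_label is None:
        positive_label = sorted(map(str, classes))[-1]
    assignment = _stratified_folds(y, k, seed)
    fold_metrics: list[EvalMetrics] = []
    confusions: list[ConfusionMatrix] = []
    for fold in range(k):
        test = assignment == fold
        if not test.any():
            raise ValueError("empty test fold; reduce k")
        if len(np.unique(y[~test])) < 2:
            raise ValueError("a training fold lost a class; reduce k")
        model = train_model(X[~test], y[~test], spec, seed)
        pred = model.predict(X[test])
        truth = y[test]
        is_pos = np.asarray([str(t) == str(positive_label) for t in truth])
        pred_pos = np.asarray([str(p) == str(positive_label) for p in pred])
        cm = ConfusionMatrix(
            tp=int(np.sum(is_pos & pred_pos)),
            fp=int(np.sum(~is_pos & pred_pos)),
            tn=int(np.sum(~is_pos & ~pred_pos)),
            fn=int(np.sum(is_pos & ~pred_pos)),
        )
        confusions.append(cm)
        fold_metrics.append(metrics(cm))
    return CVResult(fold_metrics=fold_metrics, fold_assignment=assignment,
                    confusions=confusions)


def run_tasks(dataset: LabeledDataset, fs: float,
              spec: ModelSpec | None = None, tfd_kind: str = "embd",
              k: int = 5, seed: int = 0,
              features_by_label: dict | None = None) -> dict[str, CVResult]:
    """Evaluate the two binary MI tasks on a three-class dataset.

    Task "stemi": NORMAL vs ST_ELEVATION; task "nstemi": NORMAL vs
    T_INVERSION. Both use the same fold protocol and the named TFD for
    the joint features. ``features_by_label`` may supply precomputed
    per-class feature frames (as from :func:`features.feature_matrix`) to
    avoid recomputing TFDs.
    """
    from .features import feature_matrix  # deferred: avoids import cycle

    spec = spec or ModelSpec()
    counts = dataset.class_counts
    for needed in (BeatLabel.NORMAL, BeatLabel.ST_ELEVATION, BeatLabel.T_INVERSION):
        if counts.get(needed, 0) == 0:
            raise ValueError(f"dataset is missing class {needed.value}")
    if features_by_label is None:
        all_feats = feature_matrix(dataset.matrix, fs, tfd_kind)
        labels = np.asarray([lab.value for lab in dataset.labels])
        features_by_label = {
            lab: all_feats[labels == lab.value].to_numpy() for lab in counts
        }
    results = {}
    for task, abnormal in (("stemi", BeatLabel.ST_ELEVATION),
                           ("nstemi", BeatLabel.T_INVERSION)):
        Xn = np.asarray(features_by_label[BeatLabel.NORMAL], dtype=float)
        Xa = np.asarray(features_by_label[abnormal], dtype=float)
        X = np.vstack([Xn, Xa])
        y = np.array([BeatLabel.NORMAL.value] * len(Xn) + [abnormal.value] * len(Xa))
        X = np.nan_to_num(X, nan=0.0)
        results[task] = cross_validate(X, y, spec, k=k, seed=seed,
                                       positive_label=abnormal.value)
    return results
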