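"""Time-domain, frequency-domain and joint time-frequency features, plus
per-feature ROC/AUC screening.

The five statistical features use population (1/N) moments: mean,
variance, skewness, non-excess kurtosis (m4 / sigma^4) and coefficient of
variation. Where a moment is undefined (zero variance, or zero mean for
the CV) the value is reported as NaN rather than raising, so whole
feature matrices stay rectangular.

Spectral features operate on the positive-frequency magnitude spectrum:
flatness (geometric over arithmetic mean, 1 for white spectra, 0 for a
line spectrum), normalized Shannon entropy of the power spectrum, and
flux (mean squared frame-to-frame change of the magnitude spectrum over
25%-length frames with 50% overlap).

Joint (t, f) variants extend the same eight statistics to a quadratic
TFD: the five moments over the flattened TFD magnitude (so mean and
variance scale as a^2 and a^4 under input scaling, the normalized shape
moments are scale-free), and the three spectral features per time slice,
averaged over time (flux across consecutive slices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import mannwhitneyu

from .qtfd import TFDMatrix, compute_tfd

T_FEATURE_NAMES = ["mean", "variance", "skewness", "kurtosis", "coeff_variation"]
F_FEATURE_NAMES = ["spectral_flux", "spectral_entropy", "spectral_flatness"]
JOINT_FEATURE_NAMES = [f"tf_{name}" for name in T_FEATURE_NAMES + F_FEATURE_NAMES]
ALL_FEATURE_NAMES = T_FEATURE_NAMES + F_FEATURE_NAMES + JOINT_FEATURE_NAMES

_TINY = 1e-300


def t_features(x: np.ndarray) -> dict[str, float]:
    """Population-moment statistics of a sequence."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    m = float(np.mean(x))
    d = x - m
    var = float(np.mean(d ** 2))
    if var > 0:
        sigma = np.sqrt(var)
        skew = float(np.mean(d ** 3) / sigma ** 3)
        kurt = float(np.mean(d ** 4) / sigma ** 4)
        cv = sigma / m if m != 0 else float("nan")
    else:
        skew = kurt = cv = float("nan")
    return {"mean": m, "variance": var, "skewness": skew,
            "kurtosis": kurt, "coeff_variation": cv}


def _spectral_flatness(mag: np.ndarray) -> float:
    mag = np.asarray(mag, dtype=float)
    am = np.mean(mag)
    if am == 0:
        return float("nan")
    gm = np.exp(np.mean(np.log(mag + _TINY)))
    return float(gm / am)


def _spectral_entropy(power: np.ndarray) -> float:
    power = np.asarray(power, dtype=float)
    total = power.sum()
    k = len(power)
    if total == 0 or k < 2:
        return float("nan")
    p = power / total
    return float(-np.sum(xlogy(p, p)) / np.log(k))


def _spectral_flux(frames_mag: np.ndarray) -> float:
    """Mean over consecutive frames of sum((|X_t| - |X_{t-1}|)^2)."""
    if frames_mag.shape[0] < 2:
        return float("nan")
    diff = np.diff(frames_mag, axis=0)
    return float(np.mean(np.sum(diff ** 2, axis=1)))


def f_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Spectral flux, normalized spectral entropy and spectral flatness.

    Flatness and entropy are computed over the strictly positive
    frequency bins of the whole trace; flux over short frames (25% of the
    trace, 50% overlap).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("trace too short for spectral features")
    mag = np.abs(np.fft.rfft(x))[1:]  # strictly positive frequencies
    sf = _spectral_flatness(mag)
    se = _spectral_entropy(mag ** 2)
    frame_len = max(int(round(0.25 * n)), 4)
    hop = max(frame_len // 2, 1)
    starts = range(0, n - frame_len + 1, hop)
    frames = np.stack([np.abs(np.fft.rfft(x[s:s + frame_len]))[1:] for s in starts])
    flux = _spectral_flux(frames)
    return {"spectral_flux": flux, "spectral_entropy": se,
            "spectral_flatness": sf}


def joint_tf_features(tfd: TFDMatrix) -> dict[str, float]:
    """The eight statistics extended to a TFD matrix (see module docs)."""
    v = np.abs(np.asarray(tfd.values, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("TFD contains non-finite values")
    if v.sum() == 0:
        raise ValueError("all-zero TFD")
    stats = t_features(v.ravel())
    row_sums = v.sum(axis=1)
    live = v[row_sums > 0]
    if len(live):
        # vectorized per-slice flatness and entropy
        am = live.mean(axis=1)
        gm = np.exp(np.mean(np.log(live + _TINY), axis=1))
        sf = float(np.mean(gm / am))
        p = live / live.sum(axis=1, keepdims=True)
        se = float(np.mean(-xlogy(p, p).sum(axis=1) / np.log(live.shape[1])))
    else:
        sf = se = float("nan")
    out = {f"tf_{k}": val for k, val in stats.items()}
    out["tf_spectral_flatness"] = sf
    out["tf_spectral_entropy"] = se
    out["tf_spectral_flux"] = _spectral_flux(v)
    return out


def extract_features(x: np.ndarray, fs: float, tfd_kind: str = "embd",
                     **tfd_kwargs) -> dict[str, float]:
    """Full 16-element feature vector (5 t-domain, 3 f-domain, 8 joint)
    for one trace, with the joint features taken from the named TFD."""
    out: dict[str, float] = {}
    out.update(t_features(x))
    out.update(f_features(x, fs))
    out.update(joint_tf_features(compute_tfd(x, fs, tfd_kind, **tfd_kwargs)))
    return {name: out[name] for name in ALL_FEATURE_NAMES}


def feature_matrix(traces: np.ndarray, fs: float, tfd_kind: str = "embd",
                   **tfd_kwargs) -> pd.DataFrame:
    """Feature table for a stack of equal-length traces (rows)."""
    rows = [extract_features(tr, fs, tfd_kind, **tfd_kwargs) for tr in traces]
    return pd.DataFrame(rows, columns=ALL_FEATURE_NAMES)


# ---------------------------------------------------------------------------
# ROC / AUC screening


def feature_auc(values_pos: np.ndarray, values_neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a positive sample exceeds
    a negative one, ties counted one half."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def folded_auc(auc: float) -> float:
    """Direction-folded AUC, max(auc, 1 - auc), so anti-correlated
    features screen on the strength of their separation."""
    return max(auc, 1.0 - auc)


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    auc: float
    auc_folded: float
    selected: bool


def screen_features(features: pd.DataFrame, labels: np.ndarray,
                    positive_label, min_auc: float = 0.5) -> list[FeatureScore]:
    """Per-feature ROC screening of positives vs the rest.

    Features with undefined values in either group are scored NaN and not
    selected. Selection uses the folded AUC against an inclusive
    threshold.
    """
    labels = np.asarray(labels)
    pos_mask = labels == positive_label
    if not pos_mask.any() or pos_mask.all():
        raise ValueError("need both positive and negative samples")
    report = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        pos, neg = col[pos_mask], col[~pos_mask]
        if np.isnan(pos).any() or np.isnan(neg).any():
            report.append(FeatureScore(name, float("nan"), float("nan"), False))
            continue
        auc = feature_auc(pos, neg)
        fold = folded_auc(auc)
        report.append(FeatureScore(name, auc, fold, fold >= min_auc))
    return report


def select_features(report: list[FeatureScore], min_auc: float = 0.5) -> list[str]:
    """Names of features whose folded AUC meets the inclusive threshold."""
    if not report:
        raise ValueError("empty feature report")
    return [r.feature for r in report
            if not np.isnan(r.auc_folded) and r.auc_folded >= min_auc]
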