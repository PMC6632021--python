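"""Digital filtering and baseline-wander correction.

The chain mirrors a wearable single-lead front end: a short moving-average
FIR smoother, a two-stage running-median baseline estimator (200 ms to
knock out QRS complexes and P waves, then 600 ms to remove T waves) whose
output is subtracted from the smoothed signal, and a digital 50 Hz notch.
All filters are length-preserving and use reflect padding at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import butter, filtfilt, iirnotch


@dataclass(frozen=True)
class PreprocessConfig:
    ma_window_ms: float = 20.0
    median1_ms: float = 200.0
    median2_ms: float = 600.0
    notch_freq_hz: float = 50.0
    notch_q: float = 30.0
    bandpass_hz: tuple[float, float] = (0.48, 41.0)

    def __post_init__(self) -> None:
        if self.ma_window_ms <= 0 or self.median1_ms <= 0:
            raise ValueError("window widths must be > 0")
        if self.median2_ms <= self.median1_ms:
            raise ValueError("median2_ms must exceed median1_ms")


def _odd(n: int) -> int:
    """Round to the nearest odd integer >= 1 (symmetric window with a
    centre sample)."""
    n = max(int(round(n)), 1)
    return n if n % 2 == 1 else n + 1


def moving_average(samples: np.ndarray, window_len: int) -> np.ndarray:
    """Centred moving mean, length-preserving, reflect-padded edges."""
    x = np.asarray(samples, dtype=float)
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len > len(x):
        raise ValueError("window_len exceeds signal length")
    if window_len == 1:
        return x.copy()
    return uniform_filter1d(x, size=int(window_len), mode="reflect")


def estimate_baseline(samples: np.ndarray, fs: float,
                      cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Baseline-wander estimate via a 200 ms / 600 ms running-median cascade.

    The first median is wide enough to suppress QRS complexes and P waves,
    the second removes T waves; what survives is the slow drift.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(samples, dtype=float)
    if len(x) / fs * 1000.0 <= cfg.median2_ms:
        raise ValueError("record shorter than the 600 ms baseline window")
    w1 = _odd(cfg.median1_ms * fs / 1000.0)
    w2 = _odd(cfg.median2_ms * fs / 1000.0)
    stage1 = median_filter(x, size=w1, mode="reflect")
    return median_filter(stage1, size=w2, mode="reflect")


def correct_baseline(samples: np.ndarray, fs: float,
                     cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Moving-average smoothing followed by subtraction of the median-cascade
    baseline estimate. Invariant to additive constants."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(samples, dtype=float)
    w = max(int(round(cfg.ma_window_ms * fs / 1000.0)), 1)
    smoothed = moving_average(x, min(w, len(x)))
    return smoothed - estimate_baseline(smoothed, fs, cfg)


def notch_50hz(samples: np.ndarray, fs: float,
               cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency (default 50 Hz, Q=30)."""
    cfg = cfg or PreprocessConfig()
    if fs <= 2 * cfg.notch_freq_hz:
        raise ValueError("fs must exceed twice the notch frequency")
    b, a = iirnotch(cfg.notch_freq_hz, cfg.notch_q, fs=fs)
    return filtfilt(b, a, np.asarray(samples, dtype=float))


def bandpass(samples: np.ndarray, fs: float,
             cfg: PreprocessConfig | None = None, order: int = 2) -> np.ndarray:
    """Optional zero-phase band-pass matching the analog front end's
    0.48-41 Hz corners, for raw synthetic input that never saw hardware."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.bandpass_hz
    b, a = butter(order, [lo, hi], btype="band", fs=fs)
    return filtfilt(b, a, np.asarray(samples, dtype=float))


def preprocess(samples: np.ndarray, fs: float,
               cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Standard chain: notch, then baseline correction. Use this signal
    for delineation (it has a true zero level for the J/I zero-crossing
    searches)."""
    cfg = cfg or PreprocessConfig()
    return correct_baseline(notch_50hz(samples, fs, cfg), fs, cfg)


def front_end(samples: np.ndarray, fs: float,
              cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Notch plus moving-average smoothing only — the measurement signal.

    Running-median baseline subtraction treats any sustained ST shift as
    baseline and removes most of it, so absolute level measurements
    (isoelectric vs ST comparison, beat segmentation for the feature
    pipeline) are made on this lightly filtered signal instead; the
    per-beat differential ``st - iso`` cancels slow wander on its own.
    """
    cfg = cfg or PreprocessConfig()
    x = notch_50hz(samples, fs, cfg)
    w = max(int(round(cfg.ma_window_ms * fs / 1000.0)), 1)
    return moving_average(x, min(w, len(x)))
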