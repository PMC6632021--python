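"""Linear (threshold-rule) myocardial-infarction detection.

Per beat, the isoelectric level (median of the 20 ms PR segment ending at
the I point) is compared with the ST level (mean over the J-K span); the
ST deviation ``st - iso`` against clinical-style thresholds (default
0.10 mV, i.e. 1 mm at standard 10 mm/mV gain) flags ST elevation or
depression, and the T amplitude relative to the isoelectric level flags
T-wave inversion. Stream classification slides a 10 s window one mean
interbeat interval at a time and takes the majority beat label per
window, breaking ties toward the more severe label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import (DelineationConfig, FiducialSet, detect_r_peaks,
                        heart_rate, locate_fiducials)
from .preprocess import PreprocessConfig, front_end, preprocess
from .records import BeatLabel, ECGRecord

#: Severity order used for tie-breaking (most severe first).
SEVERITY = (BeatLabel.ST_ELEVATION, BeatLabel.ST_DEPRESSION,
            BeatLabel.T_INVERSION, BeatLabel.NORMAL)


@dataclass(frozen=True)
class LinearThresholds:
    st_elev_mv: float = 0.10
    st_depr_mv: float = 0.10
    t_inv_mv: float = 0.05

    def __post_init__(self) -> None:
        if min(self.st_elev_mv, self.st_depr_mv, self.t_inv_mv) <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class StreamConfig:
    window_s: float = 10.0
    iso_segment_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


@dataclass(frozen=True)
class BeatLevels:
    iso_mv: float
    st_mv: float
    t_mv: float  # T amplitude relative to the isoelectric level

    @property
    def st_deviation_mv(self) -> float:
        return self.st_mv - self.iso_mv


@dataclass(frozen=True)
class LinearDecision:
    start_s: float
    end_s: float
    iso_level_mv: float
    st_level_mv: float
    st_deviation_mv: float
    t_amplitude_mv: float
    label: BeatLabel
    n_beats: int


def iso_st_levels(samples: np.ndarray, fs: float, fid: FiducialSet,
                  iso_segment_ms: float = 20.0) -> BeatLevels:
    """Isoelectric, ST and T levels for one delineated beat.

    iso = median over the ``iso_segment_ms`` PR segment ending at I;
    st = mean over [J, K]; t = amplitude at the T point minus iso.
    Invariant to additive constants by construction (all three levels
    shift together; the deviations do not).
    """
    if fid.i is None or fid.j is None or fid.k is None or fid.t is None:
        raise ValueError("beat is missing required fiducials (I, J, K, T)")
    x = np.asarray(samples, dtype=float)
    n_iso = max(int(round(iso_segment_ms * fs / 1000.0)), 1)
    lo = max(fid.i - n_iso + 1, 0)
    iso = float(np.median(x[lo:fid.i + 1]))
    st = float(np.mean(x[fid.j:fid.k + 1]))
    t = float(x[fid.t] - iso)
    return BeatLevels(iso_mv=iso, st_mv=st, t_mv=t)


def classify_beat_linear(levels: BeatLevels,
                         thr: LinearThresholds | None = None) -> BeatLabel:
    """Threshold rule per beat; ST states take precedence over the T state."""
    thr = thr or LinearThresholds()
    dev = levels.st_deviation_mv
    if not np.isfinite([levels.iso_mv, levels.st_mv, levels.t_mv]).all():
        raise ValueError("levels must be finite")
    if dev > thr.st_elev_mv:
        return BeatLabel.ST_ELEVATION
    if dev < -thr.st_depr_mv:
        return BeatLabel.ST_DEPRESSION
    if levels.t_mv < -thr.t_inv_mv:
        return BeatLabel.T_INVERSION
    return BeatLabel.NORMAL


def _majority_with_severity(labels: list[BeatLabel]) -> BeatLabel:
    counts = {lab: labels.count(lab) for lab in set(labels)}
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    for lab in SEVERITY:  # most severe first
        if lab in tied:
            return lab
    return BeatLabel.NORMAL


def classify_stream_linear(
    record: ECGRecord,
    cfg: StreamConfig | None = None,
    thr: LinearThresholds | None = None,
    pre_cfg: PreprocessConfig | None = None,
    delin_cfg: DelineationConfig | None = None,
) -> list[LinearDecision]:
    """Sliding-window linear classification of a whole record.

    Windows are ``window_s`` seconds long and advance by one mean
    interbeat interval (adjacent beat-aligned windows therefore overlap
    by all but one interval). Each window's label is the majority over
    the complete beats inside it, ties broken toward severity.
    """
    cfg = cfg or StreamConfig()
    thr = thr or LinearThresholds()
    if record.duration_s < cfg.window_s:
        raise ValueError("record shorter than one analysis window")
    x = preprocess(record.samples, record.fs, pre_cfg)
    x_meas = front_end(record.samples, record.fs, pre_cfg)
    r = detect_r_peaks(x, record.fs, delin_cfg)
    if r.size == 0:
        raise ValueError("no beats detected")
    fids = locate_fiducials(x, record.fs, r, delin_cfg)
    beats = []
    for fid in fids:
        try:
            lv = iso_st_levels(x_meas, record.fs, fid, cfg.iso_segment_ms)
        except ValueError:
            continue
        beats.append((fid.r / record.fs, lv, classify_beat_linear(lv, thr)))
    if not beats:
        raise ValueError("no complete beats in record")
    advance = 60.0 / heart_rate(r, record.fs) if r.size >= 2 else cfg.window_s
    decisions: list[LinearDecision] = []
    start = 0.0
    while start + cfg.window_s <= record.duration_s + 1e-9:
        end = start + cfg.window_s
        inside = [(t, lv, lab) for t, lv, lab in beats if start <= t < end]
        if inside:
            labels = [lab for _, _, lab in inside]
            decisions.append(LinearDecision(
                start_s=start,
                end_s=end,
                iso_level_mv=float(np.mean([lv.iso_mv for _, lv, _ in inside])),
                st_level_mv=float(np.mean([lv.st_mv for _, lv, _ in inside])),
                st_deviation_mv=float(np.mean([lv.st_deviation_mv for _, lv, _ in inside])),
                t_amplitude_mv=float(np.mean([lv.t_mv for _, lv, _ in inside])),
                label=_majority_with_severity(labels),
                n_beats=len(inside),
            ))
        start += advance
    if not decisions:
        raise ValueError("no windows contained complete beats")
    return decisions
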