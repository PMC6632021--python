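"""Wavelet R-peak detection and fiducial-point delineation.

R peaks are found on the undecimated (a-trous) dyadic wavelet transform of
the preprocessed signal at scale 2**4, where QRS energy dominates and
fine-scale noise has died out. The wavelet is the quadratic-spline pair
standard in ECG delineation; the detector thresholds the coefficient
modulus at a fraction (default 0.6) of its maximum within each 10 s
analysis window — Tompkins-style adaptive thresholding — enforces a
refractory period, and refines each candidate to the raw-signal extremum
inside half a QRS width.

Around each R peak the remaining fiducials are located from the
baseline-corrected signal:

* Q and S — signal minima within 32 ms before / after R;
* J — first return to the isoelectric zero level after S (QRS end);
* T — largest absolute deflection between 80 ms after J and 400 ms after
  R (absolute, so inverted T waves are found too);
* K — 35 ms before the T peak, i.e. near T onset: the end of the ST
  measurement span (the ST segment runs J to K);
* I, P, H — the mirrored construction before the QRS: first return to
  zero before Q, the P peak, and the point 35 ms after P. The H-I span
  is the PR isoelectric reference line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Quadratic-spline filter pair for the a-trous dyadic transform.
QSPLINE_LOWPASS = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
QSPLINE_HIGHPASS = np.array([2.0, -2.0])


@dataclass(frozen=True)
class DelineationConfig:
    wavelet_scale: int = 4          # dyadic level, i.e. scale 2**4
    r_threshold: float = 0.6        # fraction of per-window coefficient max
    qrs_ms: float = 60.0
    qs_window_ms: float = 32.0
    t_from_r_ms: float = 400.0
    t_after_j_ms: float = 80.0
    k_from_t_ms: float = 35.0
    refractory_ms: float = 200.0
    iso_deadband_mv: float = 0.02
    analysis_window_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        for name in ("qrs_ms", "qs_window_ms", "t_from_r_ms",
                     "t_after_j_ms", "k_from_t_ms", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices (0-based); ``None`` marks a point
    whose search window fell outside the record. Only R is mandatory."""

    r: int
    p: int | None = None
    q: int | None = None
    s: int | None = None
    t: int | None = None
    h: int | None = None
    i: int | None = None
    j: int | None = None
    k: int | None = None

    @property
    def complete(self) -> bool:
        return all(v is not None
                   for v in (self.p, self.q, self.s, self.t,
                             self.h, self.i, self.j, self.k))

    def ordered(self) -> bool:
        """Check the fiducial ordering P <= H <= I <= Q < R < S <= J <= K < T
        over the points that are present."""
        seq = [self.p, self.h, self.i, self.q, self.r,
               self.s, self.j, self.k, self.t]
        present = [v for v in seq if v is not None]
        return all(a <= b for a, b in zip(present, present[1:]))


def _upsampled(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert 2**(level-1) - 1 zeros between taps (a-trous upsampling)."""
    step = 2 ** (level - 1)
    if step == 1:
        return filt
    out = np.zeros((len(filt) - 1) * step + 1)
    out[::step] = filt
    return out


def _conv_centered(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Length-preserving centred convolution with reflect padding."""
    pad = len(filt)
    xp = np.pad(x, pad, mode="reflect")
    full = np.convolve(xp, filt, mode="full")
    start = pad + (len(filt) - 1) // 2
    return full[start:start + len(x)]


def equivalent_filter(level: int) -> np.ndarray:
    """Composed FIR filter of the scale-2**level dyadic transform
    (cascade of upsampled low-pass stages and the final high-pass)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    eq = np.array([1.0])
    for j in range(1, level):
        eq = np.convolve(eq, _upsampled(QSPLINE_LOWPASS, j))
    return np.convolve(eq, _upsampled(QSPLINE_HIGHPASS, level))


def dyadic_wt(samples: np.ndarray, level: int) -> np.ndarray:
    """Undecimated dyadic wavelet coefficients at scale 2**level.

    Same length as the input and linear in it; equals centred convolution
    with :func:`equivalent_filter` away from the edges.
    """
    x = np.asarray(samples, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    support = len(equivalent_filter(level))
    if len(x) < support:
        raise ValueError(f"record shorter than the scale-2^{level} filter support")
    s = x
    w = None
    for j in range(1, level + 1):
        w = _conv_centered(s, _upsampled(QSPLINE_HIGHPASS, j))
        s = _conv_centered(s, _upsampled(QSPLINE_LOWPASS, j))
    return w


def detect_r_peaks(samples: np.ndarray, fs: float,
                   cfg: DelineationConfig | None = None) -> np.ndarray:
    """Detect R peaks; returns sorted sample indices.

    Coefficient-modulus maxima above ``r_threshold`` x (window max) are
    kept largest-first under a refractory period, then snapped to the
    raw-signal maximum within half a QRS width. Detection is invariant to
    global amplitude scaling (the threshold is relative) and to additive
    constants (the wavelet has zero mean).
    """
    cfg = cfg or DelineationConfig()
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    try:
        w = dyadic_wt(x, cfg.wavelet_scale)
    except ValueError:
        return np.array([], dtype=int)
    a = np.abs(w)
    # per-window relative threshold
    thr = np.empty_like(a)
    win = max(int(round(cfg.analysis_window_s * fs)), 1)
    for start in range(0, len(a), win):
        seg = a[start:start + win]
        thr[start:start + win] = cfg.r_threshold * seg.max()
    # local maxima of the modulus above threshold
    interior = (a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:])
    cand = np.flatnonzero(interior) + 1
    cand = cand[(a[cand] > thr[cand]) & (a[cand] > 0)]
    if cand.size == 0:
        return np.array([], dtype=int)
    # refractory: keep strongest first
    refr = int(round(cfg.refractory_ms * fs / 1000.0))
    kept: list[int] = []
    for c in cand[np.argsort(a[cand])[::-1]]:
        if all(abs(c - k) >= refr for k in kept):
            kept.append(int(c))
    # snap to the raw-signal maximum within +-qrs_ms/2
    half = int(round(cfg.qrs_ms / 2 * fs / 1000.0))
    peaks = set()
    for c in kept:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.add(int(lo + np.argmax(x[lo:hi])))
    out = np.array(sorted(peaks), dtype=int)
    # snapping can merge neighbours; enforce refractory once more
    if out.size > 1:
        keep = [0]
        for idx in range(1, len(out)):
            if out[idx] - out[keep[-1]] >= refr:
                keep.append(idx)
            elif x[out[idx]] > x[out[keep[-1]]]:
                keep[-1] = idx
        out = out[keep]
    return out


def _first_zero_after(x: np.ndarray, start: int, stop: int, dead: float) -> int | None:
    for idx in range(start, min(stop, len(x))):
        if x[idx] >= -dead:
            return idx
    return None


def _first_zero_before(x: np.ndarray, start: int, stop: int, dead: float) -> int | None:
    for idx in range(start, max(stop, -1), -1):
        if x[idx] >= -dead:
            return idx
    return None


def locate_fiducials(samples: np.ndarray, fs: float, r_indices: np.ndarray,
                     cfg: DelineationConfig | None = None) -> list[FiducialSet]:
    """Locate the remaining fiducial points around each detected R peak.

    Expects a baseline-corrected signal (the zero level is the isoelectric
    reference). Points whose search windows fall outside the record are
    left absent; that is the contract, not an error.
    """
    cfg = cfg or DelineationConfig()
    x = np.asarray(samples, dtype=float)
    ms = fs / 1000.0
    w_qs = int(round(cfg.qs_window_ms * ms))
    w_t = int(round(cfg.t_from_r_ms * ms))
    w_tj = int(round(cfg.t_after_j_ms * ms))
    w_k = int(round(cfg.k_from_t_ms * ms))
    dead = cfg.iso_deadband_mv
    out: list[FiducialSet] = []
    for r in np.asarray(r_indices, dtype=int):
        fid = FiducialSet(r=int(r))
        # Q, S: minima inside the 32 ms windows flanking R
        if r - w_qs >= 0:
            fid.q = int(r - w_qs + np.argmin(x[r - w_qs:r]))
        if r + w_qs < len(x):
            fid.s = int(r + 1 + np.argmin(x[r + 1:r + w_qs + 1]))
        # J: first return to the zero level after the (negative) S wave
        if fid.s is not None:
            fid.j = _first_zero_after(x, fid.s + 1, r + w_t, dead)
        # T: largest absolute deflection in [J + 80 ms, R + 400 ms]
        if fid.j is not None:
            t_lo, t_hi = fid.j + w_tj, r + w_t
            if t_lo < t_hi <= len(x):
                seg = x[t_lo:t_hi]
                fid.t = int(t_lo + np.argmax(np.abs(seg)))
        # K: ST-segment end, 35 ms short of the T peak
        if fid.t is not None and fid.j is not None and fid.t - w_k >= fid.j:
            fid.k = fid.t - w_k
        # mirrored construction before the QRS
        if fid.q is not None:
            fid.i = _first_zero_before(x, fid.q - 1, r - w_t, dead)
        if fid.i is not None:
            p_lo, p_hi = r - w_t, fid.i - w_tj
            if 0 <= p_lo < p_hi:
                fid.p = int(p_lo + np.argmax(x[p_lo:p_hi]))
        # H: isoelectric-segment start, 35 ms past the P peak
        if fid.p is not None and fid.i is not None and fid.p + w_k <= fid.i:
            fid.h = fid.p + w_k
        out.append(fid)
    return out


def heart_rate(r_indices: np.ndarray, fs: float) -> float:
    """Mean heart rate in bpm from the R-peak train: 60 / mean(RR seconds)."""
    r = np.asarray(r_indices, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two R peaks")
    rr_s = np.diff(r) / fs
    return 60.0 / float(np.mean(rr_s))
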