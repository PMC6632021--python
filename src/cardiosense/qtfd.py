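"""Quadratic time-frequency distributions: WVD, spectrogram, EMBD.

All three distributions are computed on the analytic signal (negative
frequencies removed, which halves the cross-term clutter) and share one
axis convention: time step 1/fs, frequency axis 0..fs/2 over ``n_freq``
bins, and a scaling such that

    sum(values) * dt * df  ~=  sum(x**2) / fs

i.e. the matrix integrates to the energy of the real input signal. The
number of frequency bins defaults to the next power of two >= 2N.

The discrete Wigner-Ville distribution is built from the lag-indexed
instantaneous autocorrelation K[n, m] = z[n+m] * conj(z[n-m]) (true lag
2m/fs) followed by an FFT over m; it is real by conjugate symmetry of K.

The EMBD (extended modified B-distribution) filters K in the ambiguity
(Doppler-lag) domain with the separable kernel

    G(nu, tau) = |Gamma(beta + j pi nu)|^2 / Gamma(beta)^2
               * |Gamma(alpha + j pi tau)|^2 / Gamma(alpha)^2

with Doppler nu and lag tau both on normalized [-1/2, 1/2) grids, so
G(0, 0) = 1 and G -> 1 everywhere as alpha, beta -> infinity (EMBD -> WVD).
Small alpha, beta concentrate the kernel near the ambiguity-domain origin,
where auto-terms live, and suppress the oscillatory cross-terms.

The spectrogram is the squared magnitude of a hop-1 short-time Fourier
transform with a unit-energy Hann window; it is non-negative everywhere
but smears sharp events by the window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.special import gammaln, loggamma


@dataclass(frozen=True)
class EMBDParams:
    """Lag (alpha) and Doppler (beta) kernel shape parameters; smaller
    values smooth more. Defaults of 0.1 give strong cross-term
    suppression while keeping auto-term resolution useful for one-beat
    ECG traces."""

    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")


@dataclass
class TFDMatrix:
    """Time x frequency energy density."""

    values: np.ndarray  # (n_times, n_freq), real
    fs: float
    kind: str  # "WVD" | "SPEC" | "EMBD"

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_freq) * self.fs / (2.0 * self.n_freq)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def df(self) -> float:
        return self.fs / (2.0 * self.n_freq)

    def energy(self) -> float:
        """sum(values) * dt * df."""
        return float(np.sum(self.values) * self.dt * self.df)


def signal_energy(x: np.ndarray, fs: float) -> float:
    """Discrete-time energy sum(x**2)/fs, the quantity the TFDs conserve."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x ** 2) / fs)


def _next_pow2(n: int) -> int:
    return 1 << max(int(n) - 1, 0).bit_length()


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic (negative-frequency-free) extension of a real signal."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    return hilbert(x)


def _lag_autocorr(z: np.ndarray, n_fft: int) -> np.ndarray:
    """Instantaneous autocorrelation K[n, m] = z[n+m] conj(z[n-m]) placed
    in FFT order along the lag axis (width n_fft, zero where n+-m leaves
    the record)."""
    n = len(z)
    m_max = (n - 1) // 2
    K = np.zeros((n, n_fft), dtype=complex)
    idx_n = np.arange(n)[:, None]
    m = np.arange(m_max + 1)[None, :]
    valid = (idx_n - m >= 0) & (idx_n + m < n)
    plus = np.where(valid, idx_n + m, 0)
    minus = np.where(valid, idx_n - m, 0)
    prod = np.where(valid, z[plus] * np.conj(z[minus]), 0.0)
    K[:, :m_max + 1] = prod
    K[:, n_fft - m_max:] = np.conj(prod[:, 1:][:, ::-1])
    return K


def wvd(x: np.ndarray, fs: float, n_freq: int | None = None) -> TFDMatrix:
    """Discrete Wigner-Ville distribution of a real signal."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    z = analytic_signal(x)
    n_fft = n_freq or _next_pow2(2 * len(x))
    K = _lag_autocorr(z, n_fft)
    V = np.fft.fft(K, axis=1)
    values = np.real(V) / fs
    return TFDMatrix(values=values, fs=fs, kind="WVD")


def spec(x: np.ndarray, fs: float, window_len: int | None = None,
         n_freq: int | None = None) -> TFDMatrix:
    """Spectrogram (hop-1 STFT magnitude squared, unit-energy Hann window)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    if window_len is None:
        window_len = max((n // 4) | 1, 5)
    if not 1 <= window_len <= n:
        raise ValueError("window_len must be in [1, len(x)]")
    if window_len % 2 == 0:
        window_len += 1
    z = analytic_signal(x)
    w = np.hanning(window_len + 2)[1:-1]
    w = w / np.sqrt(np.sum(w ** 2))  # unit energy
    n_fft = n_freq or _next_pow2(2 * n)
    half = window_len // 2
    # periodic extension: hop-1 frames then tile every sample with total
    # window weight exactly sum(w^2) = 1, so energy is conserved by
    # Parseval once negative-frequency leakage is folded back
    zp = np.pad(z, half, mode="wrap")
    frames = np.lib.stride_tricks.sliding_window_view(zp, window_len) * w
    F = np.fft.fft(frames, n=2 * n_fft, axis=1)
    values = np.abs(F[:, :n_fft]) ** 2
    values[:, 1:] += np.abs(F[:, n_fft + 1:][:, ::-1]) ** 2
    values /= 2.0 * fs
    return TFDMatrix(values=values, fs=fs, kind="SPEC")


def embd_kernel(n_times: int, n_fft: int, params: EMBDParams,
                n_lag_norm: int) -> tuple[np.ndarray, np.ndarray]:
    """Doppler and lag kernel factors g1(nu), g2(tau) on the FFT grids.

    Both arguments are normalized to [-1/2, 1/2): Doppler in cycles per
    sample over the time axis, lag as m / n_lag_norm.
    """
    nu = np.fft.fftfreq(n_times)
    g1 = np.exp(2.0 * np.real(loggamma(params.beta + 1j * np.pi * nu))
                - 2.0 * gammaln(params.beta))
    m = np.fft.fftfreq(n_fft) * n_fft  # signed lag index per FFT column
    tau = np.clip(m / n_lag_norm, -0.5, 0.5)
    g2 = np.exp(2.0 * np.real(loggamma(params.alpha + 1j * np.pi * tau))
                - 2.0 * gammaln(params.alpha))
    return g1, g2


def embd(x: np.ndarray, fs: float, params: EMBDParams | None = None,
         n_freq: int | None = None) -> TFDMatrix:
    """Extended modified B-distribution.

    The instantaneous autocorrelation is taken to the ambiguity domain by
    an FFT over time, multiplied by the separable gamma-function kernel,
    brought back, and Fourier-transformed over lag exactly as the WVD.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    params = params or EMBDParams()
    z = analytic_signal(x)
    n = len(x)
    n_fft = n_freq or _next_pow2(2 * n)
    K = _lag_autocorr(z, n_fft)
    g1, g2 = embd_kernel(n, n_fft, params, n_lag_norm=n)
    A = np.fft.fft(K, axis=0)          # time -> Doppler
    A *= g1[:, None]
    A *= g2[None, :]
    Kf = np.fft.ifft(A, axis=0)        # Doppler -> time
    V = np.fft.fft(Kf, axis=1)         # lag -> frequency
    values = np.real(V) / fs
    return TFDMatrix(values=values, fs=fs, kind="EMBD")


_KINDS = {"wvd": wvd, "spec": spec, "embd": embd}


def compute_tfd(x: np.ndarray, fs: float, kind: str, **kwargs) -> TFDMatrix:
    """Dispatch by kind name ('wvd', 'spec' or 'embd')."""
    try:
        fn = _KINDS[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown TFD kind {kind!r}") from None
    return fn(x, fs, **kwargs)
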