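"""Synthetic single-lead ECG generation and device-emulation utilities.

The beat model is a sum of Gaussian bumps, one per wave (P, Q, R, S, T),
each with an amplitude in mV, a width in ms and a centre offset from the
R peak in ms — the classic phenomenological alternative to dynamical-system
generators, adequate for morphology-level work on ST/T pathology. Three
beat classes are provided:

* normal — upright T, isoelectric ST segment;
* ST elevation (STEMI-like) — a smooth positive plateau added between the
  end of the S wave and the onset of the T wave;
* T inversion (NSTEMI-like) — the T bump multiplied by -1.

Wearable-noise components (baseline wander, 50 Hz powerline, broadband
EMG, motion-artifact transients) and a 10-bit / 3.0 V ADC model emulate
the acquisition chain of a chest-worn single-lead device sampling at
500 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import BeatAnnotation, BeatLabel, ECGRecord

# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: amplitude (mV), width (ms, ~2 sigma), centre
    offset from the R peak (ms)."""

    amplitude_mv: float
    width_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("wave width must be > 0")


@dataclass(frozen=True)
class BeatMorphology:
    """Per-wave parameters of one beat plus the ST/T pathology knobs.

    ``st_offset_mv`` is added as a smooth plateau over the span between the
    end of the S wave and the onset of the T wave; ``t_sign`` multiplies
    the T bump (-1 gives an inverted T).
    """

    p: WaveParams = WaveParams(0.15, 25.0, -180.0)
    q: WaveParams = WaveParams(-0.10, 10.0, -25.0)
    r: WaveParams = WaveParams(1.00, 12.0, 0.0)
    s: WaveParams = WaveParams(-0.15, 10.0, 25.0)
    t: WaveParams = WaveParams(0.30, 60.0, 300.0)
    st_offset_mv: float = 0.0
    t_sign: int = +1

    def __post_init__(self) -> None:
        if self.t_sign not in (+1, -1):
            raise ValueError("t_sign must be +1 or -1")

    @property
    def waves(self) -> dict[str, WaveParams]:
        return {"p": self.p, "q": self.q, "r": self.r, "s": self.s, "t": self.t}


def morphology_for(label: BeatLabel | str, st_offset_mv: float = 0.2) -> BeatMorphology:
    """Canonical morphology for a beat class.

    ST classes use ``st_offset_mv`` (elevation positive, depression
    negative); T inversion flips the T wave.
    """
    label = BeatLabel(label)
    if label == BeatLabel.NORMAL:
        return BeatMorphology()
    if label == BeatLabel.ST_ELEVATION:
        return BeatMorphology(st_offset_mv=abs(st_offset_mv))
    if label == BeatLabel.ST_DEPRESSION:
        return BeatMorphology(st_offset_mv=-abs(st_offset_mv))
    if label == BeatLabel.T_INVERSION:
        return BeatMorphology(t_sign=-1)
    raise ValueError(f"invalid label {label!r}")


def subject_morphology(label: BeatLabel | str, rng: np.random.Generator,
                       amp_cv: float = 0.15, width_cv: float = 0.10,
                       t_shift_ms: float = 15.0,
                       st_offset_mv: float = 0.2) -> BeatMorphology:
    """Draw one synthetic subject's beat morphology.

    Real cohorts show marked inter-patient variability in wave amplitudes,
    widths and timing; a dataset of identical beats would make the
    classification task trivially easy. Amplitudes and widths get
    independent multiplicative jitter (coefficients of variation
    ``amp_cv`` and ``width_cv``), the T wave shifts by up to
    ``t_shift_ms``, and pathological ST offsets vary by the same
    amplitude jitter.
    """
    base = morphology_for(label, st_offset_mv=st_offset_mv)

    def jitter(w: WaveParams, dt: float = 0.0) -> WaveParams:
        return WaveParams(
            amplitude_mv=w.amplitude_mv * max(1 + amp_cv * rng.standard_normal(), 0.4),
            width_ms=w.width_ms * max(1 + width_cv * rng.standard_normal(), 0.5),
            offset_ms=w.offset_ms + dt,
        )

    dt_t = float(np.clip(t_shift_ms * rng.standard_normal(), -t_shift_ms, t_shift_ms))
    st = base.st_offset_mv * max(1 + amp_cv * rng.standard_normal(), 0.4)
    return BeatMorphology(
        p=jitter(base.p), q=jitter(base.q), r=jitter(base.r),
        s=jitter(base.s), t=jitter(base.t, dt_t),
        st_offset_mv=st, t_sign=base.t_sign,
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Additive wearable-noise model.

    Defaults describe a reasonably clean chest-belt recording: 0.1 mV
    respiratory baseline wander at 0.3 Hz, 0.05 mV residual 50 Hz mains
    pickup, 0.02 mV RMS broadband EMG. Motion artifacts (raised-cosine
    bumps at random times) are off by default and enabled per experiment.
    """

    baseline_amp: float = 0.10
    baseline_freq: float = 0.30
    powerline_amp: float = 0.05
    emg_sigma: float = 0.02
    motion_rate: float = 0.0  # events per minute
    motion_amp: float = 1.0
    motion_width_ms: float = 100.0  # impulsive electrode transients
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "powerline_amp", "emg_sigma",
                     "motion_rate", "motion_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Named noise presets for the CLI and examples.
NOISE_PRESETS: dict[str, NoiseConfig] = {
    "none": NoiseConfig(baseline_amp=0.0, powerline_amp=0.0, emg_sigma=0.0),
    "default": NoiseConfig(),
    "motion": NoiseConfig(motion_rate=12.0, motion_amp=1.2),
}


@dataclass(frozen=True)
class ADCConfig:
    """Successive-approximation ADC model: ``bits`` resolution over a
    0..``vref`` volt range, mid-rail offset for bipolar signals."""

    bits: int = 10
    vref: float = 3.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("bits must be >= 1")
        if self.vref <= 0:
            raise ValueError("vref must be > 0")

    @property
    def n_codes(self) -> int:
        return 2 ** self.bits

    @property
    def step_v(self) -> float:
        """Quantization step in volts (LSB size)."""
        return self.vref / self.n_codes

    @property
    def step_mv(self) -> float:
        return 1000.0 * self.step_v


@dataclass(frozen=True)
class PowerBudget:
    """Battery capacity (mAh), continuous load (mA) and a derating factor
    for real-world losses (default 0.70)."""

    capacity_mah: float
    load_ma: float
    derating: float = 0.70

    def __post_init__(self) -> None:
        if self.capacity_mah < 0 or self.load_ma < 0:
            raise ValueError("capacity and load must be >= 0")
        if not 0 < self.derating <= 1:
            raise ValueError("derating must be in (0, 1]")


# ---------------------------------------------------------------------------
# beat and record synthesis


def _gauss(t_ms: np.ndarray, wave: WaveParams) -> np.ndarray:
    sigma = wave.width_ms / 2.0
    return wave.amplitude_mv * np.exp(-0.5 * ((t_ms - wave.offset_ms) / sigma) ** 2)


def st_plateau_span_ms(morph: BeatMorphology) -> tuple[float, float]:
    """(start, end) of the ST plateau in ms relative to the R peak: from
    the end of the S bump to the onset of the T bump."""
    start = morph.s.offset_ms + morph.s.width_ms
    end = morph.t.offset_ms - morph.t.width_ms
    return start, end


def generate_beat(morph: BeatMorphology, fs: float, rr_ms: float) -> np.ndarray:
    """Synthesize one beat of ``round(rr_ms * fs / 1000)`` samples.

    The R peak sits at the centre sample; each wave is a Gaussian bump at
    its offset; the ST offset enters as a raised-cosine-edged plateau
    between the end of S and the onset of T; T is multiplied by ``t_sign``.
    """
    if fs <= 0 or rr_ms <= 0:
        raise ValueError("fs and rr_ms must be > 0")
    offsets = [w.offset_ms for w in morph.waves.values()]
    if rr_ms / 2 < max(abs(o) for o in offsets):
        raise ValueError("rr_ms too short to span the wave offsets")
    n = int(round(rr_ms * fs / 1000.0))
    t_ms = (np.arange(n) - n // 2) * 1000.0 / fs  # 0 at the R centre
    beat = np.zeros(n)
    for name, wave in morph.waves.items():
        if name == "t":
            wave = replace(wave, amplitude_mv=morph.t_sign * wave.amplitude_mv)
        beat += _gauss(t_ms, wave)
    if morph.st_offset_mv != 0.0:
        lo, hi = st_plateau_span_ms(morph)
        edge = 20.0  # ms raised-cosine transition on each side
        ramp_up = 0.5 * (1 - np.cos(np.pi * np.clip((t_ms - (lo - edge)) / edge, 0, 1)))
        ramp_dn = 0.5 * (1 + np.cos(np.pi * np.clip((t_ms - hi) / edge, 0, 1)))
        beat += morph.st_offset_mv * ramp_up * ramp_dn
    return beat


def beat_r_offset(fs: float, rr_ms: float) -> int:
    """Index of the R-peak sample within one generated beat."""
    return int(round(rr_ms * fs / 1000.0)) // 2


def _motion_artifacts(n: int, fs: float, noise: NoiseConfig,
                      rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    duration_min = n / fs / 60.0
    n_events = rng.poisson(noise.motion_rate * duration_min)
    half = int(round(noise.motion_width_ms * fs / 1000.0 / 2))
    for center in rng.integers(0, n, size=n_events):
        lo, hi = max(0, center - half), min(n, center + half)
        t = np.arange(lo, hi) - center
        out[lo:hi] += noise.motion_amp * 0.5 * (1 + np.cos(np.pi * t / max(half, 1)))
    return out


def generate_record(
    label: BeatLabel | str,
    n_beats: int,
    morph: BeatMorphology | None = None,
    noise: NoiseConfig | None = None,
    adc: ADCConfig | None = None,
    fs: float = 500.0,
    mean_bpm: float = 60.0,
    rr_jitter: float = 0.0,
    record_id: str | None = None,
) -> ECGRecord:
    """Generate a labelled synthetic record of ``n_beats`` concatenated beats.

    RR intervals are ``60000/mean_bpm`` ms with multiplicative Gaussian
    jitter of relative SD ``rr_jitter``; noise components are added on top
    of the beat train; if ``adc`` is given the samples are passed through
    the quantizer and mapped back to mV. Each R centre is annotated with
    the class label. Identical ``noise.seed`` gives bitwise-identical
    output.
    """
    label = BeatLabel(label)
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if morph is None:
        morph = morphology_for(label)
    if noise is None:
        noise = NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    base_rr = 60000.0 / mean_bpm
    pieces: list[np.ndarray] = []
    r_indices: list[int] = []
    pos = 0
    for _ in range(n_beats):
        rr = base_rr * (1.0 + rr_jitter * rng.standard_normal()) if rr_jitter else base_rr
        rr = max(rr, 2.1 * max(abs(w.offset_ms) for w in morph.waves.values()))
        beat = generate_beat(morph, fs, rr)
        r_indices.append(pos + beat_r_offset(fs, rr))
        pieces.append(beat)
        pos += len(beat)
    x = np.concatenate(pieces)
    n = len(x)
    t = np.arange(n) / fs
    if noise.baseline_amp:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t + phase)
    if noise.powerline_amp:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + noise.powerline_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if noise.emg_sigma:
        x = x + noise.emg_sigma * rng.standard_normal(n)
    if noise.motion_rate:
        x = x + _motion_artifacts(n, fs, noise, rng)
    if adc is not None:
        codes = quantize_adc(x / 1000.0, adc)  # mV -> V
        x = dequantize_adc(codes, adc) * 1000.0
    anns = [BeatAnnotation(i, label) for i in r_indices]
    return ECGRecord(
        record_id=record_id or f"synthetic-{label.value.lower()}",
        fs=fs,
        samples=x,
        annotations=anns,
    )


# ---------------------------------------------------------------------------
# ADC and power models


def quantize_adc(volts: np.ndarray, adc: ADCConfig,
                 bipolar: bool = True) -> np.ndarray:
    """Quantize a voltage signal to integer ADC codes.

    With ``bipolar=True`` (the ECG front-end case) a mid-rail offset of
    ``vref/2`` first maps the signal into the converter's 0..vref range;
    with ``bipolar=False`` the input is taken as already unipolar. Then
    ``code = floor(v / step)`` clipped to ``[0, 2**bits - 1]``; clipping
    (saturation) is the contract, not an error.
    """
    v = np.asarray(volts, dtype=float)
    if bipolar:
        v = v + adc.vref / 2.0
    codes = np.floor(v / adc.step_v).astype(np.int64)
    return np.clip(codes, 0, adc.n_codes - 1)


def dequantize_adc(codes: np.ndarray, adc: ADCConfig,
                   bipolar: bool = True) -> np.ndarray:
    """Map integer codes back to volts (bin-centre reconstruction)."""
    v = (np.asarray(codes, dtype=float) + 0.5) * adc.step_v
    return v - adc.vref / 2.0 if bipolar else v


def battery_life(budget: PowerBudget) -> float:
    """Runtime in hours: ``capacity / load * derating``."""
    if budget.load_ma <= 0:
        raise ValueError("load_ma must be > 0")
    return budget.capacity_mah / budget.load_ma * budget.derating


def required_capacity(hours: float, load_ma: float, derating: float = 0.70) -> float:
    """Battery capacity (mAh) needed to sustain ``load_ma`` for ``hours``."""
    if derating <= 0:
        raise ValueError("derating must be > 0")
    return hours * load_ma / derating
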