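# Methods

This note records the models, conventions and numerical choices behind
cardiosense, and where the design was genuinely open, why it was settled
the way it was. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic ECG model

A beat is a sum of five Gaussian bumps — P, Q, R, S, T — each with an
amplitude (mV), width (ms, ≈ 2σ) and centre offset from the R peak (ms).
Defaults: P(0.15 mV, 25 ms, −180 ms), Q(−0.10, 10, −25), R(1.00, 12, 0),
S(−0.15, 10, +25), T(0.30, 60, +300). Pathology enters through two knobs:
`st_offset_mv` adds a raised-cosine-edged plateau between the end of the
S bump and the onset of the T bump (+0.2 mV default for the ST-elevation
class, negative for depression), and `t_sign = −1` inverts the T wave
(the T-inversion class). The R peak sits at the centre sample of each
beat; RR intervals take multiplicative Gaussian jitter.

Noise components model a chest-worn single-supply front end at 500 Hz:

| component | default | unit | meaning |
|---|---|---|---|
| baseline wander | 0.10 mV at 0.30 Hz | sinusoid | respiration/electrode drift |
| powerline | 0.05 mV at 50 Hz | sinusoid | residual mains pickup |
| EMG | 0.02 mV RMS | white Gaussian | muscle noise |
| motion | off by default; preset: 1.2 mV, 12/min, 100 ms | raised-cosine bumps at Poisson times | impulsive electrode artifacts |

Motion transients are deliberately short (100 ms): the documented failure
mode of threshold-rule classifiers comes from impulsive artifacts with
enough mid-band energy to disturb the wavelet detector's per-window
threshold, not from slow smooth excursions, which the median-cascade
baseline correction absorbs. The motion preset's rate (12/min) is chosen
so a five-minute demonstration record reliably exhibits mislabelled
windows across random seeds; at lower rates the majority-vote window
rule absorbs isolated events on some seeds.

Per-subject variability: `subject_morphology` draws each synthetic
subject's wave amplitudes (CV 0.15), widths (CV 0.10), T-wave timing
(±15 ms) and pathological ST offset (CV 0.15); cohort construction also
draws a per-subject heart rate (55–85 bpm) and RR jitter 0.05. Real
cohorts vary markedly between patients, and without this the three-class
task is so easy that every feature family saturates and comparisons
between them are meaningless.

What the generator does **not** emulate: real QRS micro-morphology
(notching, bundle-branch shapes), respiration-modulated RR dynamics,
rhythm disturbances, electrode-contact dropouts, and the full diversity
of clinical ST/T morphologies. Passing tests on this data shows the
pipeline's mechanics are correct and self-consistent; it does not
certify clinical performance.

Device emulation: ADC codes are `floor(v/step)` with step = vref/2^bits
(2.93 mV at 10 bits / 3.0 V), mid-rail offset vref/2 for bipolar input,
saturating at the rails; reconstruction is bin-centred, so round-trip
error is bounded by one step. Battery life is capacity/load × 0.70, the
derating covering real-world losses.

## Preprocessing

Moving-average FIR (20 ms, centred, reflect-padded) smooths broadband
noise. Baseline is estimated by a running-median cascade — 200 ms to
remove QRS and P, then 600 ms to remove T — and subtracted; widths are
rounded to odd sample counts so windows are symmetric. A zero-phase IIR
notch (Q = 30) removes 50 Hz; an optional 0.48–41 Hz band-pass mirrors
an analog front end for raw synthetic input.

A deliberate two-signal convention runs through the pipeline. The
median cascade treats any **sustained** ST shift as baseline and removes
most of it (a 0.2 mV plateau survives only as ~0.02 mV). Delineation
therefore runs on the fully corrected signal, whose true zero level the
J/I zero-crossing searches need, while level measurement (iso vs ST) and
beat segmentation use the notch + moving-average signal only. The
measured deviation st − iso is a within-beat difference, so slow wander
largely cancels without baseline subtraction.

## Delineation

The dyadic wavelet transform is the à-trous (undecimated) cascade of the
quadratic-spline pair h = [1, 3, 3, 1]/8, g = [2, −2], taken to scale 2⁴
where QRS energy dominates at 500 Hz. Filters are upsampled by zero
insertion; each stage uses centred, reflect-padded convolution, and the
cascade equals one convolution with the composed equivalent filter away
from the edges (a tested identity). R candidates are modulus maxima
above 0.6 × the per-10 s-window maximum — the relative threshold makes
detection amplitude- and offset-invariant — kept strongest-first under a
200 ms refractory period and snapped to the raw-signal maximum within
±30 ms (half the nominal 60 ms QRS width).

Fiducials around each R: Q/S are minima within ±32 ms windows; J is the
first sample after S back at the zero level (a ±0.02 mV dead band keeps
the crossing robust to residual noise); T is the **largest absolute**
deflection in [J+80 ms, R+400 ms] — absolute, because an inverted T is a
minimum and the T-inversion class must be detectable; K is 35 ms before
the T peak, i.e. near T onset, ending the ST measurement span. Mirrored
before the QRS: I is the last zero return before Q, P the maximum in
[R−400 ms, I−80 ms], H is 35 ms after P, so H–I frames the PR
isoelectric segment. The per-beat ordering P ≤ H ≤ I ≤ Q < R < S ≤ J ≤ K
< T is enforced; a point whose window leaves the record is absent and
the beat is flagged incomplete rather than erroring. (Two geometric
readings exist for the 35 ms K/H construction — toward or away from the
QRS; only the toward-QRS placement makes the J–K span an ST segment and
leaves a flat-ST beat with near-zero measured deviation, so that is the
one implemented.)

## Linear classification

iso = median over the 20 ms PR segment ending at I (median, not mean,
for robustness to residual P-tail); st = mean over [J, K]; T amplitude
is measured relative to iso. Thresholds default to 0.10 mV for ST
deviation — the clinical 1 mm at standard 10 mm/mV gain — and 0.05 mV
for T inversion; ST states take precedence over the T state. Windows are
10 s, advance one mean interbeat interval, and take the majority beat
label with ties resolved toward severity (ST elevation > ST depression >
T inversion > normal). These threshold values and the aggregation rule
are design choices; the window length and half-interval overlap mirror
the streaming protocol.

## Quadratic TFDs

Conventions shared by all three distributions: computed on the analytic
signal (scipy Hilbert transform) to suppress cross-terms between
positive and negative frequencies; frequency axis 0…fs/2 over n_freq
bins, n_freq = next power of two ≥ 2N; time step 1/fs, Δf =
fs/(2·n_freq); scaling such that Σ values · Δt · Δf equals the signal
energy Σx²/fs (exactly up to the DC/Nyquist part that an analytic signal
cannot carry — zero-mean traces conserve to well under 1%).

WVD: K[n, m] = z[n+m] z*[n−m] for |m| ≤ min(n, N−1−n) (no lag window),
FFT over m; real by conjugate symmetry, and verified equal to the
brute-force double-sum definition to 1e−9 on short signals.

Spectrogram: hop-1 STFT with a unit-energy Hann window (default length
N/4, forced odd), periodic signal extension so every sample carries
total window weight exactly 1, and the small negative-frequency leakage
of windowed analytic frames folded back onto the positive bins — both
choices exist to make energy conservation exact by Parseval rather than
approximate.

EMBD: the ambiguity function (FFT of K over time) is multiplied by the
separable kernel G(ν, τ) = |Γ(β + jπν)|²/Γ(β)² · |Γ(α + jπτ)|²/Γ(α)²
with Doppler ν and lag τ both on normalized [−½, ½) grids (τ = m/N),
then brought back and transformed over lag like the WVD. G(0,0) = 1 by
construction, G → 1 (EMBD → WVD) as α, β → ∞, and small parameters
concentrate the kernel near the ambiguity origin where auto-terms live.
Defaults α = β = 0.1 are a common choice in the quadratic-TFD
literature for strong cross-term suppression; they are exposed in
`EMBDParams` and recorded with any run that uses them. Kernel magnitudes
use log-gamma arithmetic for numerical stability.

## Features

Time-domain statistics are population (1/N) moments, kurtosis non-excess
(m₄/σ⁴); undefined cases (zero variance; zero mean for CV) yield NaN
sentinels so feature matrices stay rectangular. Spectral features use
the strictly positive frequency bins: flatness = geometric/arithmetic
mean of the magnitude spectrum, entropy = Shannon entropy of the
normalized power spectrum divided by log K, flux = mean squared
frame-to-frame magnitude-spectrum change over frames of 25% of the trace
with 50% overlap (the framing fractions are design choices).

Joint (t, f) extension — the construction was genuinely open, and two
readings of "moments over the TFD" exist: statistics of the cell
*values*, or moments of the (t, f) *position* under the normalized mass.
The value-statistics reading is implemented: the five moments are
computed over the flattened un-normalized TFD magnitude, which makes
mean and variance covariant with the squared input scale (×a², ×a⁴) and
the shape statistics scale-free, while flatness and entropy are computed
per time slice on the slice's magnitude profile and averaged (both
scale-invariant), and joint flux is the slice-to-slice squared change.
One consequence worth knowing: a two-tone signal, spreading equal energy
over more cells, has *lower* joint value-variance than a single tone —
the opposite of what the positional reading would give.

AUC screening is the Mann–Whitney probability that a positive sample
exceeds a negative one (ties ½), verified against brute-force pairwise
concordance; screening uses the direction-folded max(AUC, 1−AUC) with an
inclusive 0.5 threshold, and both raw and folded values are reported.

## Classification and evaluation

Both model families standardize features inside the training fold only
(a tested no-leakage property): 3rd-degree polynomial-kernel SVM with
C = 1.0, and KNN with k = 5 and Euclidean distance — C and k are
defaults of our choosing. Folds are stratified by seeded round-robin
assignment after a per-class shuffle, which keeps fold sizes equal,
classes spread, and degenerates gracefully to leave-one-out at k = n.
Metrics come from the per-fold confusion matrix with the positive class
being the abnormal one; zero-denominator metrics are NaN for that fold
only. Means and standard deviations are taken over all five folds.

The two binary tasks are normal vs ST elevation ("stemi") and normal vs
T inversion ("nstemi"). The TFD benchmark compares feature families by
the paired mean accuracy pooled over the two tasks — a single paired
comparison per family, stabler than per-task comparisons when both
tasks sit near ceiling and fold noise is ~2 test samples.

## Real-time loop

Samples accumulate into a 10 s buffer; each full buffer is preprocessed,
delineated, segmented and classified by both binary models on EMBD
features (a buffer is labelled abnormal when more than half its beats
are), with the linear rule's mean ST deviation attached as a summary.
One decision per buffer; a partial trailing buffer is discarded with a
log notice. Alerts are debounced — at most one per contiguous abnormal
episode, re-armed by a normal decision — and delivered to pluggable sink
callables; a failing sink never blocks the others. Location is an
optional injected provider. The debounce policy and the
majority-of-beats buffer rule are design choices of this package.

## Problem sizes used

The shipped experiments are sized for a laptop-class single CPU: the
synthetic benchmark uses 600 traces per class from three subjects per
class (features for two TFD families ≈ 6 minutes), the cohort-count
reproduction assembles 3 × 7 subjects × 500 capped traces, detector
checks use five-minute records, and oracle equivalences run on signals
of ≤ 32 samples where brute force is exact.

## Known limitations

- The linear rule's ST thresholds assume a correctly recovered
  isoelectric reference; sustained artifacts longer than the PR–ST span
  defeat the within-beat cancellation.
- J-point location by zero return fails gracefully but late on deeply
  depressed ST segments (the search is capped at R+400 ms); the ST
  depression class is supported by the rule but not exercised by the
  shipped benchmark.
- EMBD cost is O(N · n_freq · log) per trace with N×n_freq intermediate
  matrices; traces much longer than ~1000 samples call for lag windowing,
  which is not implemented.
- CSV (time_s, mV) is the only record format; multi-lead montages,
  EDF/DICOM and binary waveform formats are out of scope.
- Cross-validation folds are stratified but not subject-disjoint; with
  few synthetic subjects per class, subject-disjoint folds would change
  the measured accuracies.
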