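# Methods

This note documents the models, algorithmic conventions and numerical
choices behind `physioqc`, in the order the pipeline applies them, and
states what the synthetic-data generators do and do not emulate.

## Signal model and preprocessing

All analyses operate on `UniformSignal`: a uniformly sampled single-channel
series with sampling rate `fs`, start time `t0` (sample *i* at
`t0 + i/fs`, 0-based) and unit/kind labels. Segmentation uses half-open
windows; a trailing partial window is dropped, because the aggregated SQIs
are means over windows and a short window would bias spectral estimates.

Filtering is zero-phase Butterworth (order 4, applied forward–backward with
`sosfiltfilt`), chosen so that filtering never shifts beat timing; the
effective attenuation is twice the design order. Resampling is polyphase
(with its built-in anti-alias filter) when the rate ratio is rational with
small terms, otherwise linear interpolation after an explicit anti-alias
low-pass; the method used is recorded in the signal metadata. Standardizing
z-scores the whole signal before segmentation (the pipeline order is
standardize, then segment).

Three-axis acceleration is reduced to its per-sample Euclidean norm.
Session splitting rounds marker times to the nearest sample and uses
half-open intervals; marker times must be non-decreasing, with ties allowed
so that contiguous phases can share a boundary.

## Cardiac SQIs

Kurtosis is the Pearson (non-excess) moment ratio `m₄/m₂²`: the published
good/bad thresholds (ECG > 5, BVP < 3.5, Gaussian ≈ 3) are only meaningful
on that scale. An excess-kurtosis option exists.

The spectral power ratio integrates a Welch periodogram (Hann window,
segment length min(signal, 2 s), 50% overlap) over frequency bins whose
centre lies in the half-open band [low, high); band edges above Nyquist are
truncated there. F1 ⊆ F2 is asserted at construction, which guarantees
ψ ∈ [0, 1]. The BVP broad band nominally includes DC, but the signal is
standardized (mean ≈ 0) before the PSD, so the DC bin is negligible and no
special exclusion is applied. A band that contains no PSD bins raises an
error rather than returning a silent zero. Windows where an SQI is
undefined (constant slice) are excluded from the means and counted in the
report.

## Adaptive beat detection (ECG)

The local range envelope is the per-window max − min (1 s windows, 0.5 s
overlap), evaluated at an arbitrary time as the nearest-window value (a
step-wise envelope with 0.5 s resolution). A local maximum is accepted as a
beat when the drop to the next local minimum within a 0.35 s lookahead (the
QRS downstroke scale) exceeds 0.7 × the local range at that time. Ties
between equal-height maxima resolve to the earliest. A 0.25 s refractory
period (240 bpm physiological ceiling) suppresses double detections. All
constants are keyword-configurable.

Because every quantity in the rule is relative to the signal's own local
range, detections are exactly invariant to amplitude scaling and follow
slow gain drifts — the property the algorithm exists for.

## Derivative-based pulse detection (BVP)

The signal is band-passed to [0.5, 16] Hz, differenced, and thresholded at
0.5 × the rolling 90th percentile of the *strictly positive* derivative
samples over a 10 s centred window; each maximal supra-threshold run yields
one beat at its derivative maximum (the steepest systolic upslope), subject
to the same 0.25 s refractory period. Two numerical points drove these
choices: the derivative is non-positive for most of the pulse cycle, so a
percentile over all (zero-clipped) samples sits near zero and admits the
dicrotic-notch upslope as a spurious second beat; and an upper cutoff near
the pulse bandwidth (≈8 Hz) smears the systolic rise enough that the
steepest point drifts toward the rising zero-crossing of the fundamental,
~100 ms early. With the defaults the fiducial lands ~30 ms after the true
pulse onset on clean synthetic pulses. A side effect of the centred 10 s
threshold window is that a strong artifact burst can suppress detections up
to ~5 s on either side of the burst itself.

## Adaptive outlier detection (IBI)

Sequential scan over the IBI series with a FIFO cache of the k = 5 most
recent valid IBIs, initialized (and re-initialized) to the global median of
the series. Beat *i* (the terminating endpoint of IBI *i*) is valid iff its
IBI lies within ±φ (φ = 0.25) of the cache median. After k consecutive
invalid beats the cache resets to the global median and the counter clears.
Re-initialization to the *global* median mirrors the initialization rule; a
local-median alternative was considered and rejected as under-determined
(it needs a forward-looking horizon). Invalid beats are flagged, never
deleted — downstream consumers choose the valid subset.

## Pairing validation

Detected and reference beats are matched one-to-one by greedy
nearest-distance assignment over all candidate pairs with |bd − br|
strictly less than 0.5 s (ties resolved toward the earlier reference beat).
On beat-like series (inter-beat gaps well above the tolerance) greedy
matching attains the maximum-cardinality matching; the test suite checks
this against an independent maximum-bipartite-matching oracle on 100 random
instances. On pathological inputs with many events packed inside one
tolerance window, greedy matching can be one pair short of optimal — such
inputs violate the refractory structure of heartbeats and are outside the
metric's domain.

eRMSE attributes each IBI to its terminating beat and includes a pair in
the sum only when both endpoints of the IBI are matched to the
corresponding endpoints in the reference; otherwise the IBI difference is
ill-defined. P and R are computed from the full counts regardless.

## HRV indicators

Mean IBI and RMSSD use valid IBIs only; RMSSD differences only *adjacent*
valid IBIs (a flagged beat breaks successiveness), requiring at least 10
valid IBIs. Relative HF power is the Welch power (Hann, 120 s windows, 50%
overlap, or the whole tachogram if shorter) of the cubic-spline-resampled
(4 Hz) mean-removed tachogram in [0.15, 0.4] Hz, normalized by the power in
[0.04, 0.4] Hz — the standard LF+HF denominator; both bands are
configurable. It requires a 60 s span; a zero-variance tachogram yields
hf_relative = 0 with a warning rather than a 0/0. Bland–Altman agreement is
computed on percent differences 100·(test − ref)/ref with limits of
agreement at bias ± 1.96 sd.

## EDA metrics

Preprocessing downsamples to 4 Hz (when above — clinical-grade rates are
reduced so metrics are comparable across devices) and low-passes at 1.5 Hz.

Detrending computes the 0.05 Hz low-pass of the preprocessed signal as the
trend estimate and subtracts it, yielding the fast component `sf`
(equivalent to a 0.05 Hz high-pass). The rationale: the jump and activity
metrics target fast discontinuities and phasic peaks, and an un-detrended
α would be dominated by the tonic level, defeating its purpose of flagging
absent phasic activity. A literal low-pass mode exists behind a flag for
comparison.

- `roor` counts samples strictly outside [0.05, 60] μS on the preprocessed,
  *un-detrended* signal — the range limits are absolute conductance levels.
- `nj` normalizes the first difference × fs of `sf` by the standard
  deviation of `sf` over the whole recording (a stable normalizer, making
  the count invariant to device gain) and counts maximal contiguous runs
  with |dn| > 10. A run spanning a window boundary counts once, in the
  window containing its first sample.
- `α` is the RMS of `sf` per window. The defining sum is interpreted with a
  radical (RMS, not mean square): the 0.05 μS threshold carries μS units,
  which only an RMS has. A mean-square option exists for sensitivity
  analysis.

Aggregation over non-overlapping 20 s windows: mean roor, mean α, summed
nj.

## Synthetic generators

The generators are test fixtures with controllable ground truth, not
physiologically validated simulators. What they emulate, and what they
do not:

- **Beat times**: an AR(1) IBI process (ρ = 0.5) whose innovation scale is
  set so the expected RMSSD equals the requested value; optional sinusoidal
  respiratory modulation at 0.25 Hz. `rmssd_s = 0` is an exact metronome.
  No circadian drift, ectopy or arrhythmia.
- **ECG**: per-beat Gaussian P-QRS-T deflections (R amplitude 1 mV, σ
  10 ms), 40 Hz band-limited noise (σ 5 μV) and slow baseline wander
  (0.25/0.07 Hz, ~0.04 mV). The wander guarantees every 1 s local-range
  window contains cardiac-scale amplitude; with purely white noise, windows
  far from any QRS would have a noise-dominated range, and because the ABD
  rule is scale-free, noise extremes could then exceed 0.7 × range at any
  noise amplitude. No morphology variability or electrode-pop artifacts.
- **BVP**: half-cosine systolic rise (80 ms), exponential decay (τ 0.22 s),
  dicrotic bump. The sharp rise puts the derivative maximum ~40 ms after
  the annotated onset. No respiratory amplitude modulation or venous
  oscillations.
- **EDA**: tonic level + linear drift + skin-conductance responses with 2 s
  half-cosine rise and 6 s exponential decay (the physiological ranges;
  faster shapes would trip the scale-free jump rule on clean data),
  amplitudes jittered ±30%. Onsets follow a jittered renewal process
  (interval = mean × U(0.6, 1.4)) rather than a pure Poisson process:
  real SCRs show refractory-like spacing, and the renewal process keeps the
  realized event count close to the nominal rate so that activity metrics
  reflect the requested condition rather than count dispersion. Sensor
  noise is band-limited at 0.3 Hz (device anti-alias smoothing) — again
  because the jump metric is scale-free, so only the noise's correlation
  structure matters, not its amplitude. No sweat-gland saturation dynamics
  or temperature coupling.
- **Artifacts**: motion bursts (band-limited noise with tapered edges),
  step jumps (level shift over an interval; one lasting to the end of the
  record is a single discontinuity), range saturation (clamp to a
  constant), dropouts (last-value hold). Saturation and dropout may not
  overlap.
- **Sessions**: 300 s bundles (ECG + BVP + EDA, the cardiac pair driven by
  one IBI process) per device profile; the movement phase raises heart rate
  (70 → 95 bpm) and adds the profile's artifact load (wrist wearable: heavy
  BVP/EDA motion corruption and EDA steps; chest wearable: mild ECG bursts;
  clinical: none).

All generators are pure functions of (parameters, seed), with one spawned
child stream per signal. Consequently, passing tests demonstrate that each
algorithm responds correctly to the degradation mode it targets under these
morphology templates; they do not certify performance on real recordings,
whose artifact taxonomy is richer.

## Problem sizes and defaults

Clean-signal checks use 300 s signals (ECG at 256 Hz, BVP at 64 Hz, EDA at
4 Hz); end-to-end HRV recovery uses ten 5-minute ECGs at 60 bpm with RMSSD
30 ms, recovering mean IBI within 1% and RMSSD within 10%. These sizes make
sampling error small relative to every tolerance asserted while keeping the
full suite fast.

## Known limitations

- The BVP fiducial is the steepest-upslope point, systematically ~30–40 ms
  after the pulse onset; absolute pulse-arrival timing (e.g. pulse transit
  time work) needs a different fiducial convention.
- ψ of a clean pulse wave falls below 0.5 above ~125 bpm: the harmonics at
  2f₀ and above leave F1 = [1, 2.25] Hz while remaining in F2 = [0, 8] Hz.
  The indicator's good range is calibrated for resting heart rates.
- The jump metric's σ-normalization assumes the recording contains mostly
  genuine signal; a recording consisting almost entirely of artifact
  deflates `dn` and can under-count jumps.
- `hrv_indicators` assumes the tachogram is stationary over the analysis
  span; no detrending beyond mean removal is applied before the PSD.
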