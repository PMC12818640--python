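# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the rppgkit pipeline. It is the package's own account of
its design; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Signal model and pipeline

The raw rPPG trace is the per-frame spatial mean of a colour channel over
facial ROIs (forehead, both cheeks), each tiled into k×k sub-ROIs. Tiling
does not change the mean (the pixel-count-weighted mean of disjoint tile
means equals the flat mean — a tested invariant); it exists for diagnostics
and to localise uneven illumination. The green channel is the default: it is
the most sensitive to haemoglobin absorption. Channel selection is
configurable; no cross-channel fusion rule is applied by default.

Downstream, the trace is modelled as

    g(t) = pulse(t) + drift(t) + noise(t) + artifacts(t),

with the pulse quasi-sinusoidal at the instantaneous heart rate. The
pipeline separates these components in three stages: wavelet shrinkage
(broadband noise), dual-stage zero-phase Butterworth bandpass (drift and
out-of-band noise; 0.6–3.5 Hz then 0.8–2.5 Hz, order 4 each, applied
forward–backward so peak timing is preserved), and a recursive filter over
windowed spectral heart-rate observations (in-band noise and artifacts).

## Wavelet stage

Denoising uses a Daubechies-4 multi-level DWT with symmetric extension, the
Donoho–Johnstone universal threshold T = σ√(2 ln n) with σ estimated as
MAD/0.6745 of the finest-scale details, and soft shrinkage. The
approximation is never shrunk (it carries the baseline, which the bandpass
removes).

**Band protection.** Detail levels whose dyadic band [fs/2^(j+1), fs/2^j]
overlaps the cardiac band (0.8–2.5 Hz) are exempt from shrinkage. The
universal T scales with the broadband noise level; at realistic rPPG noise
(σ comparable to the pulse amplitude) it sits at or above the magnitude of
the pulse-carrying coefficients, so shrinking the in-band levels attenuates
the pulse by an order of magnitude in power while content in the never-shrunk
approximation keeps full amplitude — on test fixtures the windowed spectral
peak then flips to approximation-band noise near 0.85 Hz. With the in-band
levels protected the denoiser is a pure out-of-band noise suppressor, its
output is insensitive to the decomposition depth J (measured MAE spread
0.016 bpm over J ∈ {3..6}), and in-band noise is handled where it belongs,
in the Kalman stage. An unprotected variant (everything shrunk, J chosen so
the approximation sits fully below the band) was evaluated and rejected: it
destroys the pulse at moderate noise. The bare `denoise()` API without
`fps`/`protect_band` applies the textbook rule to all detail levels.

The default depth J is the smallest with the approximation edge fs/2^(J+1)
at or below 0.8 Hz (J = 5 at 30 fps), clamped to [3, 6]. One global T from
the level-1 MAD is used for all shrunk levels.

## Spectral observations

Each 10 s Hann-tapered window (1 s hop, FFT zero-padded ×4 for ~0.007 Hz bin
spacing at 30 fps) yields z_k = 60·f_dom, the dominant frequency within
0.75–2.5 Hz (45–150 bpm). The 10 s window trades frequency resolution
(~0.9 bpm quantisation after padding) against temporal smearing of HR
changes; the 1 s hop makes successive observations strongly correlated,
which matters for the outlier gate below. Welch PSD is available as a
diagnostic (`rppgkit.spectral.welch_psd`, segments = window/4).

## Signal-quality index

SQ_k = λ₁·SPR + λ₂·SNR + λ₃·PS with λ = (0.3, 0.4, 0.3), each component in
[0, 1]:

- **SPR** — power within f_dom ± 0.15 Hz over total in-band power;
- **SNR** — dB ratio of (peak + first harmonic, ±0.15 Hz each) to the rest
  of the band, mapped linearly from [−10, 20] dB to [0, 1]. The harmonic is
  included because the pulse waveform is non-sinusoidal; frequency-domain
  structure is the most discriminative quality cue, hence the largest λ;
- **PS** — max(0, 1 − CV) of recent inter-beat intervals.

These constructions are this package's choices (bounded, monotone in signal
quality); only the combination rule and the λ values are fixed by the method.

## Adaptive Kalman filter

Scalar random walk, covariances in bpm². Defaults: R₀ = 25 bpm²,
Q = 0.72 bpm²/step, β = 10 bpm, α = 0.3, outlier window N = 11, c = 3,
T_out floor 5 bpm.

**On Q's units.** The published process-noise constant is 2×10⁻⁴ with no
unit. Read in bpm² it yields a steady-state gain ≈ √(Q/R₀) ≈ 0.003 — the
filter degenerates to a cumulative mean, with a tracking lag of
rate/K ≈ 180 bpm per (bpm/step of trend); it could not follow a 0.5 bpm/s
ramp at all. Read in Hz²/step — natural, since the observation is an FFT
dominant frequency — it converts to 2×10⁻⁴·60² = 0.72 bpm²/step, a random
walk of ~0.85 bpm per step that is physiologically plausible and gives a
steady-state gain ≈ 0.15. The package uses the Hz² reading as its default
(`rppgkit.rakf.PROCESS_NOISE_HZ2`); all filter equations are exact for any
Q, and the equation-level tests exercise Q = 2×10⁻⁴ directly.

**Step order.** predict → outlier gate → residual against the gated
observation → adaptive R → gain → SQ weight → update. Computing the residual
after gating avoids double-penalising a replaced outlier (its replacement is
near the prediction, so R stays near R₀).

**Outlier gate.** z̄_k is the median of the last N *raw* observations;
storing gated values instead would freeze the reference during a long
artifact and latch the gate shut once the true rate drifts away (observed on
ramp fixtures: the posterior froze 20 bpm below truth). N = 11 covers one
full analysis-window span plus one: a single 2 s artifact corrupts a run of
up to ~11 consecutive overlapping windows, and the median must straddle that
run. T_out = max(c · 1.4826·MAD(history − z̄), 5 bpm); the MAD-based scale
is used because the plain SD is inflated by the very outliers the gate must
reject. Initialisation: x̂₀ = first gated observation, P₀ = R₀.

The covariance update P_k = (1−K_k)P_k⁻ excludes the quality weight w_k, so
P keeps reflecting the noise model alone; with w < 1 the filter is
deliberately conservative (corrections shrink, stated uncertainty does not).

## HR reporting and fusion

Peaks are detected on the filtered signal with minimum distance 60/150 s,
minimum prominence 0.3× a robust amplitude (IQR/1.349·√2) and width ≥ 2
samples. The per-window time-domain rate uses the **median** inter-beat
interval: artifact bursts insert spurious high-prominence peaks, which bias
the mean IBI short (observed +13 bpm inside bursts); the median is
insertion-robust. The public `hr_from_peaks` keeps the exact mean-IBI
definitions (Δt̄, f_peak = 1/Δt̄, HR = 60·f_peak) and downstream code that
wants them can call it directly.

Fusion: HR = (sq_t·HR_time + sq_s·HR_spectral)/(sq_t + sq_s), where the
spectral-path value is the Kalman posterior and the paths' SQ values differ
only in their PS component (current window's IBIs vs a rolling buffer of
recent IBIs). If a path is absent or has zero quality the other is returned.
All emitted rates are clamped to 45–150 bpm.

## Evaluation conventions

MAE and RMSE compare the fused series against a reference aligned to window
centres by nearest-neighbour interpolation. The SNR in dB uses one
convention for raw and processed signals: the "signal" is the cardiac-band
component of the series under assessment (zero-phase 0.8–2.5 Hz Butterworth
narrowband reference), the "noise" is the remainder, both mean-centred.
A drift/noise-dominated raw trace scores negative; the pipeline output,
almost entirely in-band, scores strongly positive, and the difference is the
SNR improvement attributable to processing (24–28 dB on the default
fixtures).

## Synthetic data: what it does and does not emulate

The generator produces ground-truthed traces: pulse = fundamental + 30%
first harmonic at a configurable HR trajectory (constant, ramp, sinusoidal
modulation), baseline drift (default amplitude 1.8× pulse at 0.1 Hz),
white sensor noise (default σ = 0.7× pulse), sparse motion-artifact bursts —
boxcar-windowed low-pass-filtered (≤1.5 Hz) noise transients at 5× pulse
amplitude, whose spectral content reaches into the cardiac band as head
motion does — and a multiplicative reflectance gain mimicking
melanin-dependent amplitude. Videos embed the trace in a rectangular bright
patch on a dark background, which the default brightness-based detector
finds; the detector interface accepts any callable, and a production
deployment would plug in a trained face detector (no pretrained cascade is
bundled).

Defaults give a raw cardiac-band SNR near −5 dB — a drift-dominated
recording. What passing tests show: the pipeline recovers constant and
ramping heart rates to ~1–2.5 bpm MAE under these conditions, the stage
ablation ranks as designed, and the hyper-parameters sit on broad plateaus.
What they do not show: performance on real skin, real head motion (the
burst model is additive, not multiplicative or geometric), video
compression, or real face-detection failure modes. The noise is Gaussian
and stationary outside bursts; real sensor noise is neither.

### Problem sizes used

Tests and the acceptance script use 60 s recordings at 30 fps (the study's
recording length), 10 s/1 s windowing (51 observations per run), 20-seed
replicates for ordering checks, 100-trial denoising checks, and 1000-step
streams for the Kalman reduction check. A full acceptance run takes a few
seconds on one CPU.

## Numerical choices and edge cases

- Zero detail coefficients → T = 0 (denoising is a no-op, not an error).
- Empty observation stream → empty filter output; < 2 peaks in a window →
  the time path is absent and fusion falls back to the spectral path.
- Zero noise power in SNR → ±∞ sentinel, never an exception.
- Equality-level determinism: the pipeline has no internal randomness; the
  same trace and config give byte-identical outputs. All generator
  randomness flows through a single integer seed.
- MAE differences between pipeline variants carry estimation noise of order
  0.1 bpm at 51 windows; ordering checks treat smaller differences as ties.

## Known limitations

- The wavelet stage, with the cardiac band protected, removes only
  out-of-band noise and is therefore largely redundant with the dual-stage
  bandpass on band-limited synthetic noise; its measured marginal benefit
  here is ~0. Its practical value on real recordings (non-stationary,
  non-Gaussian noise) is not testable from the generator.
- The Kalman filter tracks ramps with a lag of ≈ rate/K ≈ 3 bpm at
  0.5 bpm/s; fusion with the unlagged time-domain path roughly halves this.
- Windows are 10 s: step changes in HR are smeared, and the first/last 5 s
  of a recording have no window centre.
- The quality index is heuristic; its λ weights are fixed, not learned.
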