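# rppgkit

Contactless heart-rate estimation from facial video by remote
photoplethysmography (rPPG), built around two signal-processing stages:
discrete-wavelet soft-threshold denoising of the raw skin-colour trace, and a
**residual-based adaptive Kalman filter (RAKF)** whose correction step is
weighted by a per-window signal-quality index.

rPPG recovers the blood-volume pulse from the tiny periodic colour changes
that each heartbeat causes in facial skin. The practical obstacles are motion
artifacts, illumination drift, and weak signal amplitude (which varies with
skin tone); this package addresses them with an explicitly adaptive filter
rather than dataset-specific tuning.

## Pipeline

1. **Acquisition** — face detection (pluggable detector interface), forehead
   and cheek ROIs tiled into sub-ROIs, per-frame spatial averaging
   `g(t) = (1/N) Σ_(i,j)∈ROI I_c(i,j,t)` for each colour channel. CLAHE
   contrast enhancement is applied only to a grayscale detection copy.
2. **Wavelet denoising** — multi-level DWT (Daubechies-4), universal
   threshold `T = σ√(2 ln n)` with `σ = MAD(d₁)/0.6745` from the finest-scale
   details, soft shrinkage `d̃ = sgn(d)(|d|−T)·1{|d|>T}`, inverse transform.
   Detail levels overlapping the cardiac band are exempt from shrinkage (see
   `docs/methods.md`).
3. **Dual-stage bandpass** — zero-phase Butterworth, wide 0.6–3.5 Hz then
   narrow 0.8–2.5 Hz.
4. **Spectral observations** — sliding 10 s Hann windows (1 s hop); the
   dominant FFT frequency in 0.75–2.5 Hz (45–150 bpm) gives the per-window
   observation `z_k = 60·f_dom`.
5. **RAKF** — scalar random-walk state `x_k = x_{k−1} + w`, observation
   `z_k = x_k + v`. Per step: median-based outlier gate
   (`|z_k − z̄_k| > T_out ⇒ z_k ← z̄_k`), residual `ỹ_k = z_k − x̂_k⁻`,
   adaptive measurement noise `R_k = R₀(1 + |ỹ_k|/β)`, gain
   `K_k = P_k⁻/(P_k⁻ + R_k)`, and the quality-weighted update
   `x̂_k = x̂_k⁻ + K_k·w_k·ỹ_k` with `w_k = max(α, SQ_k)`;
   `P_k = (1−K_k)P_k⁻` (unweighted, preserving consistency).
   `SQ_k = λ₁·SPR + λ₂·SNR + λ₃·PS` with λ = (0.3, 0.4, 0.3) combines the
   spectral power ratio, a normalised spectral SNR, and inter-beat-interval
   stability.
6. **HR reporting** — time-domain peak/IBI heart rate fused with the Kalman
   posterior by their signal-quality indices; evaluation via MAE, RMSE and a
   cardiac-band SNR in dB.

## Worked example

```python
from rppgkit import HeartRateModel
from rppgkit.synthetic import SyntheticSpec, generate_trace, default_bursts

# 60 s at 30 fps, constant 72 bpm, baseline drift, sensor noise and two
# motion-artifact bursts — a drift/noise-dominated recording
spec = SyntheticSpec(duration=60.0, fps=30.0, seed=7,
                     artifact_bursts=default_bursts(60.0))
trace, hr_true = generate_trace(spec)

res = HeartRateModel(trace).fit()
print(res.summary())
report = res.evaluate(trace.time, hr_true)
print(f"MAE  = {report.mae:.2f} bpm")
print(f"RMSE = {report.rmse:.2f} bpm")
```

prints

```
Heart-rate estimation results
==============================================
windows                                     51
window / hop (s)                 10.0      1.0
mean HR (bpm)                            71.87
HR range (bpm)                   70.6     73.6
wavelet threshold T                      2.734
raw band SNR (dB)                        -4.83
filtered band SNR (dB)                   19.48
SNR improvement (dB)                     24.31
mean signal quality SQ                   0.774
==============================================
MAE  = 0.34 bpm
RMSE = 0.61 bpm
```

The raw trace scores −4.8 dB on the cardiac-band SNR (drift and noise carry
most of its power); after denoising and filtering the signal is almost
entirely in-band (+19.5 dB). The fused per-window heart rate stays within a
fraction of a beat of the true 72 bpm despite the two artifact bursts.

The same pipeline runs from the shell:

```bash
rppgkit simulate --duration 60 --hr 72 --seed 7 --out trace.csv --truth-out truth.csv
rppgkit run --trace trace.csv --reference truth.csv --out hr.csv --report report.json
rppgkit ablate --trace trace.csv --reference truth.csv
rppgkit sensitivity --trace trace.csv --reference truth.csv
```

`rppgkit run` also accepts a directory of numbered frames (`--frames`), and
`rppgkit.acquisition.read_pure_session` reads the PURE dataset layout
(per-session PNG folder + JSON pulse ground truth). Ground-truth references
may be CSV or `.xlsx`.

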