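"""End-to-end orchestration: raw trace -> denoise -> bandpass -> observe ->
quality -> Kalman -> peak/fusion.

This module is the engine behind :class:`rppgkit.model.HeartRateModel` and
the ablation runner. ``run_from_trace`` executes the configured stages and
returns a :class:`PipelineResult` carrying every intermediate, so tests and
diagnostics can inspect each step.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import RawTrace
from .config import PipelineConfig, validate_config
from .errors import ConfigError
from .evaluation import band_snr_db
from .hr_estimation import clamp_hr, detect_peaks, fuse_estimates
from .quality import peak_stability, signal_quality, spectral_power_ratio, snr_component
from .rakf import RAKFConfig, run_filter, steps_to_frame
from .spectral import BandpassSpec, FilteredSignal, dual_stage_filter, spectral_observations
from .wavelet import WaveletSpec, default_level, denoise

log = logging.getLogger("rppgkit")

#: how many recent inter-beat intervals feed the spectral-path stability score
IBI_BUFFER = 8


@dataclass
class PipelineResult:
    """All intermediates of one pipeline run."""

    t_center: np.ndarray
    hr_time: np.ndarray  # NaN where the time path had < 2 peaks
    hr_spectral: np.ndarray
    hr_fused: np.ndarray
    sq_time: np.ndarray
    sq_spectral: np.ndarray
    raw: np.ndarray
    denoised: np.ndarray
    filtered: np.ndarray
    fps: float
    observations: list
    steps: list  # RAKF (state, StepTrace) pairs; empty for dwt_only
    snr_raw_db: float
    snr_filtered_db: float
    snr_improvement_db: float
    threshold_used: float = 0.0
    config: PipelineConfig = None

    def hr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_center_s": self.t_center,
                "hr_time_bpm": self.hr_time,
                "hr_spectral_bpm": self.hr_spectral,
                "hr_fused_bpm": self.hr_fused,
                "sq_time": self.sq_time,
                "sq_spectral": self.sq_spectral,
            }
        )

    def steps_frame(self) -> pd.DataFrame:
        return steps_to_frame(self.steps)

    def observations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [o.k for o in self.observations],
                "t_center_s": [o.t_center for o in self.observations],
                "z_bpm": [o.z for o in self.observations],
                "f_dom_hz": [o.f_dom for o in self.observations],
            }
        )


def _stage_toggles(variant: str) -> tuple[bool, bool, bool]:
    """(use_dwt, use_rakf, use_weighting) for an ablation variant."""
    return {
        "full": (True, True, True),
        "dwt_rakf_unweighted": (True, True, False),
        "rakf_weighted": (False, True, True),
        "rakf_only": (False, True, False),
        "dwt_only": (True, False, False),
    }[variant]


def run_from_trace(trace: RawTrace, config: PipelineConfig | None = None, variant: str | None = None) -> PipelineResult:
    """Run the configured pipeline stages over a raw trace."""
    config = config or PipelineConfig()
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration: " + "; ".join(violations))
    variant = variant or config.variant
    use_dwt, use_rakf, use_weighting = _stage_toggles(variant)

    raw = trace.channel(config.channel).astype(float)
    fps = trace.fps
    log.info("pipeline variant=%s: %d samples at %.1f fps", variant, len(raw), fps)

    # stage 1: wavelet denoising
    threshold_used = 0.0
    if use_dwt:
        level = config.wavelet_level or default_level(fps, config.narrow_band[0])
        den = denoise(
            raw,
            WaveletSpec(family=config.wavelet_family, level=level),
            fps=fps,
            protect_band=config.narrow_band,
        )
        denoised, threshold_used = den.values, den.threshold_used
        log.info("wavelet: family=%s level=%d T=%.4g", config.wavelet_family, level, threshold_used)
    else:
        denoised = raw.copy()

    # stage 2: dual-stage cardiac bandpass
    filtered = dual_stage_filter(
        denoised,
        fps,
        wide=BandpassSpec(*config.wide_band, order=config.filter_order),
        narrow=BandpassSpec(*config.narrow_band, order=config.filter_order),
    )

    # stage 3: windowed spectral observations
    observations = spectral_observations(
        filtered, window_length=config.window_length, hop=config.hop, search_band=config.search_band
    )
    log.info("spectral: %d observation windows", len(observations))

    # stage 4: per-window peaks + quality components
    win = int(round(config.window_length * fps))
    step = int(round(config.hop * fps))
    ibi_buffer: deque = deque(maxlen=IBI_BUFFER)
    hr_time_list: list[float] = []
    sq_time_list: list[float] = []
    sq_spec_list: list[float] = []
    for obs in observations:
        start = obs.k * step
        segment = filtered.values[start : start + win]
        peaks = detect_peaks(segment, fps=fps, hr_band_bpm=config.hr_band_bpm,
                             prominence_factor=config.prominence_factor)
        spr = spectral_power_ratio(obs.spectrum, obs.f_dom, config.search_band)
        snr = snr_component(obs.spectrum, obs.f_dom, config.search_band)
        if len(peaks) >= 2:
            ibis = np.diff(peaks.peak_times)
            # median IBI: robust to spurious peak insertions inside an
            # artifact burst, which bias the mean IBI short
            hr_t = 60.0 / float(np.median(ibis))
            in_band = config.hr_band_bpm[0] <= hr_t <= config.hr_band_bpm[1]
            hr_time_list.append(clamp_hr(hr_t, config.hr_band_bpm) if in_band else np.nan)
            ps_window = peak_stability(ibis)
            ibi_buffer.extend(ibis)
        else:
            hr_time_list.append(np.nan)
            ps_window = 0.0
        sq_time_list.append(signal_quality(spr, snr, ps_window, config.lambdas))
        ps_recent = peak_stability(np.asarray(ibi_buffer)) if len(ibi_buffer) >= 2 else ps_window
        sq_spec_list.append(signal_quality(spr, snr, ps_recent, config.lambdas))

    # stage 5: RAKF over the observation stream
    rakf_cfg = RAKFConfig(
        r0=config.r0, q=config.q, beta=config.beta, alpha=config.alpha,
        outlier_window=config.outlier_window, outlier_c=config.outlier_c,
        t_out_floor=config.t_out_floor, use_weighting=use_weighting,
    )
    if use_rakf:
        steps = run_filter(observations, sq_spec_list, rakf_cfg)
        hr_spectral = np.array([clamp_hr(s.x_hat, config.hr_band_bpm) for s, _ in steps])
    else:
        steps = []
        hr_spectral = np.array([clamp_hr(o.z, config.hr_band_bpm) for o in observations])

    # stage 6: quality-weighted fusion of the two paths
    hr_time = np.asarray(hr_time_list)
    sq_time = np.asarray(sq_time_list)
    sq_spec = np.asarray(sq_spec_list)
    if use_rakf:
        fused = np.array(
            [
                clamp_hr(
                    fuse_estimates(
                        None if np.isnan(ht) else float(ht), float(st), float(hs), float(ss)
                    ),
                    config.hr_band_bpm,
                )
                for ht, st, hs, ss in zip(hr_time, sq_time, hr_spectral, sq_spec)
            ]
        )
    else:
        fused = hr_spectral.copy()  # spectral-peak HR only, no tracking or fusion

    snr_raw = band_snr_db(raw, fps, config.narrow_band, config.filter_order)
    snr_filt = band_snr_db(filtered.values, fps, config.narrow_band, config.filter_order)

    return PipelineResult(
        t_center=np.array([o.t_center for o in observations]),
        hr_time=hr_time,
        hr_spectral=hr_spectral,
        hr_fused=fused,
        sq_time=sq_time,
        sq_spectral=sq_spec,
        raw=raw,
        denoised=np.asarray(denoised),
        filtered=filtered.values,
        fps=fps,
        observations=observations,
        steps=steps,
        snr_raw_db=snr_raw,
        snr_filtered_db=snr_filt,
        snr_improvement_db=snr_filt - snr_raw,
        threshold_used=threshold_used,
        config=config,
    )
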