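"""Model/Results interface for heart-rate estimation.

:class:`HeartRateModel` is built from data (a raw trace, a trace CSV, or a
frame sequence) plus a :class:`~rppgkit.config.PipelineConfig`; ``fit()``
executes the pipeline and returns a :class:`HeartRateResults` carrying the
per-window HR estimates, the Kalman diagnostics, the band-SNR assessment,
and a ``summary()`` table. Evaluation against a ground-truth HR series and
plotting hang off the results object.

Example
-------
>>> from rppgkit import HeartRateModel
>>> from rppgkit.synthetic import SyntheticSpec, generate_trace
>>> trace, hr_true = generate_trace(SyntheticSpec(seed=7))
>>> res = HeartRateModel(trace).fit()
>>> print(res.summary())          # doctest: +SKIP
>>> report = res.evaluate(trace.time, hr_true)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import FrameSequence, RawTrace, ROIGeometry, extract_trace
from .config import PipelineConfig, validate_config
from .errors import ConfigError, InputError
from .evaluation import EvalReport, align_reference, mae_rmse
from .pipeline import PipelineResult, run_from_trace


class HeartRateModel:
    """Heart-rate estimation model over a raw rPPG trace.

    Parameters
    ----------
    trace : RawTrace
        Per-frame channel means (from video acquisition, a CSV, or the
        synthetic generator).
    config : PipelineConfig, optional
        Stage parameters; defaults are the published operating point.
    """

    def __init__(self, trace: RawTrace, config: PipelineConfig | None = None):
        if not isinstance(trace, RawTrace):
            raise InputError("trace must be a RawTrace; use a from_* constructor")
        self.trace = trace
        self.config = config or PipelineConfig()
        violations = validate_config(self.config)
        if violations:
            raise ConfigError("invalid configuration: " + "; ".join(violations))

    # ---- constructors -----------------------------------------------------

    @classmethod
    def from_csv(cls, path, config: PipelineConfig | None = None) -> "HeartRateModel":
        """Build from a trace CSV (columns time_s, r, g, b[, n_pixels, flagged])."""
        return cls(RawTrace.from_csv(path), config)

    @classmethod
    def from_video(
        cls,
        seq: FrameSequence,
        detector,
        config: PipelineConfig | None = None,
        geometry: ROIGeometry | None = None,
        enhance: bool = False,
    ) -> "HeartRateModel":
        """Build by extracting the ROI trace from a frame sequence."""
        config = config or PipelineConfig()
        geometry = geometry or ROIGeometry(grid=config.roi_grid)
        trace = extract_trace(
            seq, detector, geometry=geometry, redetect_every=config.redetect_every, enhance=enhance
        )
        return cls(trace, config)

    # ---- fitting ----------------------------------------------------------

    def fit(self, variant: str | None = None) -> "HeartRateResults":
        """Run the pipeline; returns the results object."""
        result = run_from_trace(self.trace, self.config, variant=variant)
        return HeartRateResults(model=self, pipeline=result)


@dataclass
class HeartRateResults:
    """Fitted heart-rate series with diagnostics."""

    model: HeartRateModel
    pipeline: PipelineResult

    # ---- primary outputs --------------------------------------------------

    @property
    def t_center(self) -> np.ndarray:
        return self.pipeline.t_center

    @property
    def hr(self) -> np.ndarray:
        """Final fused heart-rate series, bpm, one value per analysis window."""
        return self.pipeline.hr_fused

    @property
    def hr_frame(self) -> pd.DataFrame:
        return self.pipeline.hr_frame()

    @property
    def mean_hr(self) -> float:
        return float(np.mean(self.pipeline.hr_fused))

    @property
    def kalman_steps(self) -> pd.DataFrame:
        return self.pipeline.steps_frame()

    @property
    def snr_raw_db(self) -> float:
        return self.pipeline.snr_raw_db

    @property
    def snr_filtered_db(self) -> float:
        return self.pipeline.snr_filtered_db

    @property
    def snr_improvement_db(self) -> float:
        return self.pipeline.snr_improvement_db

    # ---- evaluation -------------------------------------------------------

    def evaluate(self, reference_t, reference_hr) -> EvalReport:
        """Score the fused HR series against a ground-truth series.

        The reference is aligned to window centres by nearest-neighbour
        interpolation.
        """
        ref = align_reference(self.t_center, reference_t, reference_hr)
        mae, rmse = mae_rmse(self.hr, ref)
        return EvalReport(
            mae=mae,
            rmse=rmse,
            n=len(ref),
            snr_raw_db=self.snr_raw_db,
            snr_filtered_db=self.snr_filtered_db,
            snr_improvement_db=self.snr_improvement_db,
            variant=self.pipeline.config.variant if self.pipeline.config else "full",
        )

    # ---- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        p = self.pipeline
        hr = p.hr_fused
        lines = [
            "Heart-rate estimation results",
            "=" * 46,
            f"{'windows':<28}{len(hr):>18d}",
            f"{'window / hop (s)':<28}{p.config.window_length:>9.1f}{p.config.hop:>9.1f}",
            f"{'mean HR (bpm)':<28}{np.mean(hr):>18.2f}",
            f"{'HR range (bpm)':<28}{np.min(hr):>9.1f}{np.max(hr):>9.1f}",
            f"{'wavelet threshold T':<28}{p.threshold_used:>18.4g}",
            f"{'raw band SNR (dB)':<28}{p.snr_raw_db:>18.2f}",
            f"{'filtered band SNR (dB)':<28}{p.snr_filtered_db:>18.2f}",
            f"{'SNR improvement (dB)':<28}{p.snr_improvement_db:>18.2f}",
            f"{'mean signal quality SQ':<28}{np.mean(p.sq_spectral):>18.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.hr_frame.to_csv(path, index=False)

    # ---- plotting ---------------------------------------------------------

    def plot(self, reference_t=None, reference_hr=None, ax=None):
        """Plot the fused HR series (and optionally a reference) over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        ax.plot(self.t_center, self.hr, label="estimated HR", color="C0")
        obs = self.pipeline.observations_frame()
        ax.plot(obs["t_center_s"], obs["z_bpm"], ".", ms=3, alpha=0.4, label="spectral obs", color="C1")
        if reference_t is not None and reference_hr is not None:
            ax.plot(reference_t, reference_hr, "--", color="k", lw=1, label="reference")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("heart rate (bpm)")
        ax.legend(loc="best", fontsize=8)
        return ax

    def plot_signals(self, ax=None):
        """Raw vs denoised vs bandpassed signal, for a quick visual check."""
        import matplotlib.pyplot as plt

        p = self.pipeline
        t = np.arange(len(p.raw)) / p.fps
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        ax.plot(t, p.raw - np.mean(p.raw), alpha=0.4, lw=0.6, label="raw (centred)")
        ax.plot(t, p.filtered, lw=0.8, label="filtered")
        ax.set_xlabel("time (s)")
        ax.legend(loc="best", fontsize=8)
        return ax

    def plot_scalogram(self, wavelet: str = "morl", ax=None):
        """Continuous-wavelet scalogram diagnostic of the raw trace."""
        import matplotlib.pyplot as plt
        import pywt

        p = self.pipeline
        x = p.raw - np.mean(p.raw)
        freqs_target = np.linspace(0.5, 4.0, 60)
        scales = pywt.frequency2scale(wavelet, freqs_target / p.fps)
        coeffs, freqs = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / p.fps)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        t = np.arange(len(x)) / p.fps
        ax.pcolormesh(t, freqs, np.abs(coeffs) ** 2, shading="auto")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        return ax
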