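"""Time-domain peak/IBI heart rate and fusion with the spectral track.

Systolic peaks are located in the filtered signal under conventional
constraints (minimum distance = one period at 150 bpm, minimum prominence
scaled to a robust amplitude estimate, minimum width 2 samples). From the N
peak times t_1..t_N the inter-beat intervals are dt_i = t_{i+1} - t_i, the
mean interval inverts to the pulse frequency f_peak = 1/mean(dt), and
HR = 60 * f_peak.

The time-domain HR and the spectral-domain HR (here: the Kalman posterior)
are fused by their signal-quality indices,

    HR_fused = (sq_t * HR_t + sq_s * HR_s) / (sq_t + sq_s),

so the more reliable source dominates; if one estimate is absent or has zero
quality the other is returned. Emitted rates are confined to the
physiological 45–150 bpm band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError
from .spectral import FilteredSignal

HR_BAND_BPM = (45.0, 150.0)


@dataclass
class PeakSet:
    peak_times: np.ndarray  # seconds, strictly increasing
    peak_indices: np.ndarray
    constraints_used: dict

    def __len__(self) -> int:
        return len(self.peak_indices)


@dataclass
class HREstimate:
    """Per-window HR decomposition: time path, spectral path, and their fusion."""

    ibis: np.ndarray
    mean_ibi: float
    f_peak: float
    hr_time: float | None
    hr_spectral: float | None
    hr_fused: float
    sq_time: float
    sq_spectral: float


def robust_amplitude(x: np.ndarray) -> float:
    """IQR-based amplitude scale: sigma_IQR * sqrt(2) (sinusoid amplitude from its SD)."""
    q75, q25 = np.percentile(x, [75, 25])
    return float((q75 - q25) / 1.349 * np.sqrt(2.0))


def detect_peaks(
    signal: FilteredSignal | np.ndarray,
    fps: float | None = None,
    hr_band_bpm: tuple[float, float] = HR_BAND_BPM,
    prominence_factor: float = 0.3,
    min_width_samples: int = 2,
    t0: float = 0.0,
) -> PeakSet:
    """Local-maximum peak detection with distance/prominence/width constraints.

    ``min_distance`` is one beat period at the top of the HR band (60/150 s);
    ``min_prominence`` is ``prominence_factor`` times the robust amplitude of
    the window. An empty result is valid — callers fall back to the spectral
    estimate.
    """
    if isinstance(signal, FilteredSignal):
        x, fps = np.asarray(signal.values, dtype=float), signal.fps
    else:
        x = np.asarray(signal, dtype=float)
        if fps is None:
            raise InputError("fps required when passing a bare array")
    min_distance = max(1, int(round(60.0 / hr_band_bpm[1] * fps)))
    prominence = prominence_factor * robust_amplitude(x)
    constraints = {
        "min_distance_s": min_distance / fps,
        "min_prominence": prominence,
        "min_width_s": min_width_samples / fps,
    }
    if prominence <= 0 or len(x) < 3:
        return PeakSet(np.array([]), np.array([], dtype=int), constraints)
    idx, _ = find_peaks(x, distance=min_distance, prominence=prominence, width=min_width_samples)
    return PeakSet(peak_times=t0 + idx / fps, peak_indices=idx, constraints_used=constraints)


def hr_from_peaks(peaks: PeakSet) -> tuple[np.ndarray, float, float, float]:
    """(ibis, mean_ibi, f_peak, hr_time) from >= 2 detected peaks."""
    if len(peaks) < 2:
        raise InputError("need at least 2 peaks to form an inter-beat interval")
    ibis = np.diff(np.asarray(peaks.peak_times, dtype=float))
    mean_ibi = float(ibis.mean())
    f_peak = 1.0 / mean_ibi
    return ibis, mean_ibi, f_peak, 60.0 * f_peak


def fuse_estimates(
    hr_time: float | None,
    sq_time: float,
    hr_spectral: float | None,
    sq_spectral: float,
) -> float:
    """Quality-weighted convex combination of the two HR estimates."""
    t_ok = hr_time is not None and sq_time > 0.0
    s_ok = hr_spectral is not None and sq_spectral > 0.0
    if t_ok and s_ok:
        return (sq_time * hr_time + sq_spectral * hr_spectral) / (sq_time + sq_spectral)
    if t_ok:
        return float(hr_time)
    if s_ok:
        return float(hr_spectral)
    if hr_spectral is not None:
        return float(hr_spectral)
    if hr_time is not None:
        return float(hr_time)
    raise InputError("no HR estimate available from either path")


def clamp_hr(hr: float, band: tuple[float, float] = HR_BAND_BPM) -> float:
    return float(np.clip(hr, band[0], band[1]))
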