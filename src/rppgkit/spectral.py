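"""Cardiac-band isolation and windowed spectral heart-rate observations.

Two cascaded zero-phase Butterworth bandpasses refine the denoised trace: a
wide stage (0.6–3.5 Hz) strips baseline wander and high-frequency sensor
noise, then a narrow stage (0.8–2.5 Hz) confines the signal to where the
pulse fundamental lives. Zero-phase (forward–backward) application preserves
peak timing for the inter-beat-interval stage.

Heart-rate observations z_k for the Kalman filter come from sliding-window
FFTs: within each Hann-tapered window the dominant frequency f_dom inside the
physiological search band (0.75–2.5 Hz, i.e. 45–150 bpm) gives
z_k = 60 * f_dom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

#: physiological search band for the dominant cardiac frequency, Hz
DEFAULT_SEARCH_BAND = (0.75, 2.5)
WIDE_BAND = (0.6, 3.5)
NARROW_BAND = (0.8, 2.5)


@dataclass
class BandpassSpec:
    f_low: float
    f_high: float
    order: int = 4
    design: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ConfigError(f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})")
        if self.design != "butterworth":
            raise ConfigError(f"unsupported filter design {self.design!r}")

    def contains(self, other: "BandpassSpec") -> bool:
        return self.f_low <= other.f_low and other.f_high <= self.f_high


@dataclass
class FilteredSignal:
    values: np.ndarray
    stages_applied: list
    fps: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SpectralObservation:
    """One window's dominant-frequency HR observation."""

    k: int
    t_center: float
    z: float  # bpm
    f_dom: float  # Hz
    spectrum: tuple  # (frequencies Hz, power) within the search band
    window_length: float
    hop: float


def _design(spec: BandpassSpec, fps: float):
    nyq = fps / 2.0
    if spec.f_high >= nyq:
        raise ConfigError(f"upper cutoff {spec.f_high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(spec.order, [spec.f_low, spec.f_high], btype="bandpass", fs=fps, output="sos")


def bandpass(signal, spec: BandpassSpec, fps: float) -> FilteredSignal:
    """Apply one zero-phase Butterworth bandpass stage."""
    x = np.asarray(signal, dtype=float)
    sos = _design(spec, fps)
    y = sps.sosfiltfilt(sos, x) if spec.zero_phase else sps.sosfilt(sos, x)
    return FilteredSignal(values=y, stages_applied=[spec], fps=fps)


def dual_stage_filter(
    signal,
    fps: float,
    wide: BandpassSpec | None = None,
    narrow: BandpassSpec | None = None,
) -> FilteredSignal:
    """Wide then narrow bandpass in sequence; the wide band must nest the narrow."""
    wide = wide or BandpassSpec(*WIDE_BAND)
    narrow = narrow or BandpassSpec(*NARROW_BAND)
    if not wide.contains(narrow):
        raise ConfigError(
            f"narrow band ({narrow.f_low}-{narrow.f_high} Hz) not inside wide band ({wide.f_low}-{wide.f_high} Hz)"
        )
    stage1 = bandpass(signal, wide, fps)
    stage2 = bandpass(stage1.values, narrow, fps)
    return FilteredSignal(values=stage2.values, stages_applied=[wide, narrow], fps=fps)


def window_power_spectrum(segment: np.ndarray, fps: float, pad_factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, zero-padded FFT power spectrum of one analysis window."""
    seg = np.asarray(segment, dtype=float)
    seg = seg - seg.mean()
    taper = np.hanning(len(seg))
    nfft = int(2 ** np.ceil(np.log2(len(seg) * pad_factor)))
    spec = np.fft.rfft(seg * taper, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    return freqs, np.abs(spec) ** 2


def spectral_observations(
    signal: FilteredSignal,
    window_length: float = 10.0,
    hop: float = 1.0,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    pad_factor: int = 4,
) -> list[SpectralObservation]:
    """Sliding-window dominant-frequency observations z_k = 60 * f_dom.

    Windows of ``window_length`` seconds advance by ``hop`` seconds; the
    number of windows is floor((duration - window)/hop) + 1.
    """
    x = np.asarray(signal.values, dtype=float)
    fps = signal.fps
    win = int(round(window_length * fps))
    step = int(round(hop * fps))
    if win > len(x):
        raise ConfigError(f"window ({window_length}s) longer than signal ({len(x) / fps:.1f}s)")
    if step < 1:
        raise ConfigError("hop too small")
    obs: list[SpectralObservation] = []
    for k, start in enumerate(range(0, len(x) - win + 1, step)):
        freqs, power = window_power_spectrum(x[start : start + win], fps, pad_factor)
        mask = (freqs >= search_band[0]) & (freqs <= search_band[1])
        band_f, band_p = freqs[mask], power[mask]
        f_dom = float(band_f[int(np.argmax(band_p))])
        obs.append(
            SpectralObservation(
                k=k,
                t_center=(start + win / 2.0) / fps,
                z=60.0 * f_dom,
                f_dom=f_dom,
                spectrum=(band_f, band_p),
                window_length=window_length,
                hop=hop,
            )
        )
    return obs


def welch_psd(signal, fps: float, window_length: float = 10.0):
    """Welch power-spectral-density diagnostic (segments = window/4, 50% overlap)."""
    x = np.asarray(signal, dtype=float)
    nperseg = max(8, int(round(window_length * fps / 4)))
    return sps.welch(x, fs=fps, nperseg=min(nperseg, len(x)), noverlap=None)
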