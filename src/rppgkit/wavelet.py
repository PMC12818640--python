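"""Discrete-wavelet soft-threshold denoising of the raw rPPG trace.

The trace is expanded on an orthogonal discrete wavelet basis, the detail
coefficients are shrunk with Donoho–Johnstone's universal threshold

    T = sigma * sqrt(2 * ln(n)),   sigma = MAD(d_1) / 0.6745,

(sigma estimated from the finest-scale details, where the signal content is
negligible and the coefficients are essentially noise), and the signal is
rebuilt by the inverse transform. Soft thresholding zeroes coefficients with
|d| <= T and shrinks the rest toward zero by T, preserving sign. The
approximation coefficients are left untouched: they carry the baseline,
which the bandpass stage removes later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ConfigError, LevelError


@dataclass
class WaveletSpec:
    """Decomposition configuration.

    ``family`` must name an orthogonal discrete wavelet (default Daubechies-4,
    a common choice for PPG morphology). ``level`` is the maximum
    decomposition depth J; ``default_level`` picks J so the approximation band
    sits below the cardiac range.
    """

    family: str = "db4"
    level: int = 4
    threshold_rule: str = "universal"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigError("decomposition level must be >= 1")
        if self.threshold_rule != "universal":
            raise ConfigError(f"unknown threshold rule {self.threshold_rule!r}")
        try:
            w = pywt.Wavelet(self.family)
        except ValueError as exc:
            raise ConfigError(f"unknown wavelet family {self.family!r}") from exc
        if not w.orthogonal:
            raise ConfigError(f"wavelet family {self.family!r} is not orthogonal")


def default_level(fps: float, f_low: float = 0.8) -> int:
    """Depth J placing the approximation band below ``f_low`` Hz, clamped to [3, 6].

    At level J the approximation covers [0, fps / 2^(J+1)]; we take the
    smallest J putting that edge at or below f_low (0.8 Hz, the bottom of the
    cardiac band). At 30 fps this gives J = 5 (approximation 0-0.47 Hz).
    """
    j = int(np.ceil(np.log2(fps / f_low))) - 1
    return int(np.clip(j, 3, 6))


@dataclass
class WaveletDecomposition:
    approx: np.ndarray
    details: list  # details[0] is the coarsest level J, details[-1] is level 1
    spec: WaveletSpec
    n: int

    def coeff_list(self) -> list:
        return [self.approx, *self.details]


@dataclass
class DenoisedSignal:
    values: np.ndarray
    threshold_used: float
    sigma_hat: float

    def __len__(self) -> int:
        return len(self.values)


def decompose(signal, spec: WaveletSpec) -> WaveletDecomposition:
    """Multi-level DWT of a 1-D signal."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 ** spec.level:
        raise LevelError(f"signal length {len(x)} < 2^{spec.level}; reduce the decomposition level")
    coeffs = pywt.wavedec(x, spec.family, mode=spec.mode, level=spec.level)
    return WaveletDecomposition(approx=coeffs[0], details=list(coeffs[1:]), spec=spec, n=len(x))


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    out = pywt.waverec(decomp.coeff_list(), decomp.spec.family, mode=decomp.spec.mode)
    return out[: decomp.n]


def universal_threshold(detail_level1, n: int | None = None) -> tuple[float, float]:
    """Universal threshold (T, sigma_hat) from the level-1 detail coefficients.

    sigma = MAD(d_1)/0.6745 scales the median absolute deviation to the
    standard deviation of a Gaussian; T = sigma*sqrt(2 ln n) with n the
    original signal length (defaults to the coefficient count).
    """
    d = np.asarray(detail_level1, dtype=float)
    if d.size == 0:
        raise ConfigError("empty detail coefficient set")
    if n is None:
        n = d.size
    sigma = float(np.median(np.abs(d - np.median(d)))) / 0.6745
    if sigma == 0.0:
        return 0.0, 0.0
    return sigma * float(np.sqrt(2.0 * np.log(n))), sigma


def soft_threshold(d, T: float):
    """Soft shrinkage: sgn(d)*(|d|-T) where |d| > T, else 0."""
    if T < 0:
        raise ConfigError("threshold must be non-negative")
    d = np.asarray(d, dtype=float)
    out = np.sign(d) * np.maximum(np.abs(d) - T, 0.0)
    return float(out) if out.ndim == 0 else out


def level_band(fps: float, j: int) -> tuple[float, float]:
    """Nominal frequency band of detail level j: [fps/2^(j+1), fps/2^j] Hz."""
    return fps / 2.0 ** (j + 1), fps / 2.0 ** j


def denoise(
    signal,
    spec: WaveletSpec | None = None,
    fps: float | None = None,
    protect_band: tuple[float, float] | None = None,
) -> DenoisedSignal:
    """DWT -> universal threshold from level-1 details -> soft shrink -> inverse.

    A single global T (from the level-1 MAD) is applied to the detail levels;
    the approximation is passed through unchanged (it carries the baseline,
    which the bandpass removes later).

    When ``protect_band`` and ``fps`` are given, detail levels whose dyadic
    band overlaps the protected (cardiac) band are exempt from shrinkage, so
    denoising only strips out-of-band noise. The universal T scales with the
    broadband noise level, and at realistic rPPG noise it sits at or above
    the pulse coefficient magnitude: shrinking the in-band levels attenuates
    the pulse far more than the in-band noise floor, while content in the
    never-shrunk approximation keeps full amplitude and can take over the
    spectral peak. Exempting the in-band levels keeps the denoiser a pure
    out-of-band noise suppressor, makes its output insensitive to the exact
    depth J, and leaves in-band noise to the Kalman stage.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(signal, dtype=float)
    decomp = decompose(x, spec)
    T, sigma = universal_threshold(decomp.details[-1], n=decomp.n)
    new_details = []
    for i, d in enumerate(decomp.details):
        j = spec.level - i  # details[0] is the coarsest level J
        if protect_band is not None and fps is not None:
            lo, hi = level_band(fps, j)
            if lo < protect_band[1] and hi > protect_band[0]:  # in-band: keep
                new_details.append(d)
                continue
        new_details.append(soft_threshold(d, T))
    decomp.details = new_details
    values = reconstruct(decomp)
    return DenoisedSignal(values=values, threshold_used=T, sigma_hat=sigma)
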