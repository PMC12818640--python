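"""Signal-quality index SQ_k and the dynamic correction weight w_k.

The quality of a window's rPPG content is scored as a convex combination of
three bounded components,

    SQ_k = lambda1 * SPR + lambda2 * SNR + lambda3 * PS,
    lambda = (0.3, 0.4, 0.3),  sum = 1,

where SPR is the spectral power ratio (power near the dominant frequency over
total in-band power), SNR a normalised frequency-domain signal-to-noise ratio
(dominant peak plus first harmonic vs the rest of the band, mapped from
[-10, 20] dB to [0, 1]), and PS the peak stability of recent inter-beat
intervals (1 minus their coefficient of variation, floored at 0). The SNR
component carries the largest weight, frequency-domain structure being the
most discriminative indicator of rPPG reliability.

The Kalman correction weight is w_k = max(alpha, SQ_k): low-quality windows
are down-weighted but never below the floor alpha, so the filter keeps
updating under poor signal quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

DEFAULT_LAMBDAS = (0.3, 0.4, 0.3)
#: half-width of the spectral neighbourhood around f_dom, Hz
PEAK_HALF_WIDTH = 0.15
#: dB range linearly mapped onto [0, 1] for the SNR component
SNR_DB_RANGE = (-10.0, 20.0)


@dataclass
class SQComponents:
    spr: float
    snr_norm: float
    ps: float
    sq: float
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS


def spectral_power_ratio(spectrum, f_dom: float, band: tuple[float, float]) -> float:
    """Power within f_dom +/- 0.15 Hz over total in-band power, in [0, 1]."""
    freqs, power = (np.asarray(a, dtype=float) for a in spectrum)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    total = float(power[in_band].sum())
    if total <= 0.0:
        return 0.0
    near = in_band & (np.abs(freqs - f_dom) <= PEAK_HALF_WIDTH)
    return float(np.clip(power[near].sum() / total, 0.0, 1.0))


def snr_component(spectrum, f_dom: float, band: tuple[float, float] | None = None) -> float:
    """Normalised spectral SNR: (peak + first harmonic) vs remaining band power.

    The dB ratio is mapped linearly from [-10, 20] dB onto [0, 1] with
    clipping; zero residual power maps to 1.
    """
    freqs, power = (np.asarray(a, dtype=float) for a in spectrum)
    if band is None:
        band = (float(freqs.min()), float(freqs.max()))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    sig_mask = in_band & (
        (np.abs(freqs - f_dom) <= PEAK_HALF_WIDTH) | (np.abs(freqs - 2.0 * f_dom) <= PEAK_HALF_WIDTH)
    )
    p_sig = float(power[sig_mask].sum())
    p_noise = float(power[in_band & ~sig_mask].sum())
    if p_noise <= 0.0:
        return 1.0
    if p_sig <= 0.0:
        return 0.0
    db = 10.0 * np.log10(p_sig / p_noise)
    lo, hi = SNR_DB_RANGE
    return float(np.clip((db - lo) / (hi - lo), 0.0, 1.0))


def peak_stability(recent_ibis) -> float:
    """PS = max(0, 1 - CV) of the inter-beat intervals in the local window."""
    ibis = np.asarray(recent_ibis, dtype=float)
    if ibis.size < 2:
        return 0.0
    mean = float(ibis.mean())
    if mean <= 0.0:
        return 0.0
    cv = float(ibis.std()) / mean
    return float(max(0.0, 1.0 - cv))


def signal_quality(
    spr: float,
    snr_norm: float,
    ps: float,
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS,
) -> float:
    """SQ_k = lambda1*SPR + lambda2*SNR + lambda3*PS (weights sum to 1)."""
    lam = tuple(float(v) for v in lambdas)
    if any(v < 0 for v in lam):
        raise ConfigError("lambda weights must be non-negative")
    if abs(sum(lam) - 1.0) > 1e-9:
        raise ConfigError(f"lambda weights must sum to 1, got {sum(lam)}")
    for name, v in (("spr", spr), ("snr_norm", snr_norm), ("ps", ps)):
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name}={v} outside [0, 1]")
    return lam[0] * spr + lam[1] * snr_norm + lam[2] * ps


def dynamic_weight(sq: float, alpha: float) -> float:
    """w_k = max(alpha, SQ_k), the floored correction weight."""
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    if not 0.0 <= sq <= 1.0:
        raise ConfigError(f"sq must be in [0, 1], got {sq}")
    return max(alpha, sq)


def window_quality(
    spectrum,
    f_dom: float,
    recent_ibis,
    band: tuple[float, float],
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS,
) -> SQComponents:
    """Convenience: compute all three components and their weighted sum."""
    spr = spectral_power_ratio(spectrum, f_dom, band)
    snr = snr_component(spectrum, f_dom, band)
    ps = peak_stability(recent_ibis)
    return SQComponents(spr=spr, snr_norm=snr, ps=ps, sq=signal_quality(spr, snr, ps, lambdas), lambdas=tuple(lambdas))
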