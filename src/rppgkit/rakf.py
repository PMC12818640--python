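"""Residual-based adaptive Kalman filter (RAKF) for heart-rate tracking.

The heart rate is modelled as a scalar random walk observed through noisy
per-window spectral estimates:

    x_k = x_{k-1} + w_{k-1},  w ~ N(0, Q)
    z_k = x_k + v_k,          v ~ N(0, R_k)

Each step runs: prediction (x_prior = x_hat, P_prior = P + Q); outlier
screening of the observation against the median of the last N observations
(|z - median| > T_out replaces z by the median, with T_out = max(c * SD of
median-filtered residuals, floor)); the residual y = z - x_prior; the
adaptive measurement noise R_k = R0 * (1 + |y| / beta), which deflates the
gain when the observation disagrees with the prediction; the gain
K = P_prior / (P_prior + R_k); and the quality-weighted state update

    x_hat = x_prior + K * w_k * y,     P = (1 - K) * P_prior,

where w_k = max(alpha, SQ_k) moderates the correction by signal quality. The
covariance update deliberately excludes w_k so P keeps reflecting the
noise-model uncertainty alone.

On units: the basal measurement covariance is R0 = 25 bpm^2. The process
noise default is 0.72 bpm^2 per step — the published constant 2e-4
interpreted in Hz^2 (the observation is an FFT dominant frequency;
2e-4 Hz^2 * 60^2 = 0.72 bpm^2), which corresponds to a physiologically
plausible ~0.85 bpm/step random-walk scale. Read literally in bpm^2, 2e-4
would pin the steady-state gain near 0.003 and the filter could not track
heart-rate ramps at all. See docs/methods.md.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

#: published process-noise constant, interpreted in Hz^2/step
PROCESS_NOISE_HZ2 = 2e-4
#: the same constant expressed in bpm^2/step (x 60^2)
DEFAULT_Q_BPM2 = PROCESS_NOISE_HZ2 * 60.0 ** 2


@dataclass
class RAKFConfig:
    """Filter constants. Covariances in bpm^2; beta and T_out floor in bpm."""

    r0: float = 25.0
    q: float = DEFAULT_Q_BPM2
    beta: float = 10.0
    alpha: float = 0.3
    # one analysis-window span of observations plus one: the spectral windows
    # overlap, so a single artifact corrupts a RUN of consecutive z_k; the
    # robust reference median must span more than that run
    outlier_window: int = 11
    outlier_c: float = 3.0
    t_out_floor: float = 5.0
    adapt_r: bool = True  # residual-driven R inflation on/off
    use_weighting: bool = True  # SQ-weighted correction on/off
    handle_outliers: bool = True

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.q <= 0 or self.beta <= 0:
            raise ConfigError("R0, Q and beta must all be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.outlier_window < 1:
            raise ConfigError("outlier window must be >= 1")


@dataclass
class KalmanState:
    x_hat: float  # posterior HR estimate, bpm
    p: float  # posterior error covariance, bpm^2
    k: int = 0  # step index

    def __post_init__(self) -> None:
        if not np.isfinite(self.x_hat):
            raise ConfigError("state estimate must be finite")
        if self.p <= 0:
            raise ConfigError("error covariance must be positive")


@dataclass
class StepTrace:
    """Full diagnostic record of one filter step."""

    k: int
    z_raw: float
    z_used: float
    outlier_replaced: bool
    x_prior: float
    p_prior: float
    residual: float
    r_adaptive: float
    gain: float
    weight: float
    x_hat: float
    p: float


def predict(state: KalmanState, config: RAKFConfig) -> tuple[float, float]:
    """Random-walk prediction: x_prior = x_hat, P_prior = P + Q."""
    return state.x_hat, state.p + config.q


def adaptive_r(residual: float, config: RAKFConfig) -> float:
    """R_k = R0 * (1 + |residual| / beta); equals R0 at zero residual."""
    return config.r0 * (1.0 + abs(residual) / config.beta)


def kalman_gain(p_prior: float, r: float) -> float:
    """K = P_prior / (P_prior + R)."""
    return p_prior / (p_prior + r)


def correct_outlier(z_raw: float, history, config: RAKFConfig) -> tuple[float, bool]:
    """Replace z by the median of the last N observations when it strays.

    T_out = max(c * SD(history - median(history)), floor). With an empty
    history the observation passes through unchanged.
    """
    hist = np.asarray(list(history), dtype=float)
    if hist.size == 0 or not config.handle_outliers:
        return float(z_raw), False
    z_bar = float(np.median(hist))
    deviations = hist - z_bar
    # robust (MAD-scaled) SD: the plain SD of the deviations is itself blown
    # up by the very outliers the gate exists to reject
    robust_sd = 1.4826 * float(np.median(np.abs(deviations)))
    t_out = max(config.outlier_c * robust_sd, config.t_out_floor)
    if abs(z_raw - z_bar) > t_out:
        return z_bar, True
    return float(z_raw), False


def update(
    state: KalmanState, z_used: float, weight: float, config: RAKFConfig
) -> tuple[KalmanState, StepTrace]:
    """One full predict/adapt/update step from a screened observation.

    The residual is computed against the (possibly outlier-corrected)
    observation, so the adaptive R reflects the cleaned measurement.
    """
    x_prior, p_prior = predict(state, config)
    residual = z_used - x_prior
    r = adaptive_r(residual, config) if config.adapt_r else config.r0
    gain = kalman_gain(p_prior, r)
    x_hat = x_prior + gain * weight * residual
    p = (1.0 - gain) * p_prior
    new_state = KalmanState(x_hat=x_hat, p=p, k=state.k + 1)
    trace = StepTrace(
        k=new_state.k,
        z_raw=z_used,
        z_used=z_used,
        outlier_replaced=False,
        x_prior=x_prior,
        p_prior=p_prior,
        residual=residual,
        r_adaptive=r,
        gain=gain,
        weight=weight,
        x_hat=x_hat,
        p=p,
    )
    return new_state, trace


def run_filter(
    observations,
    sq_per_obs=None,
    config: RAKFConfig | None = None,
) -> list[tuple[KalmanState, StepTrace]]:
    """Filter a time-ordered observation stream.

    ``observations`` may be a sequence of floats (bpm) or of objects with a
    ``z`` attribute (e.g. :class:`rppgkit.spectral.SpectralObservation`).
    ``sq_per_obs`` supplies the per-observation signal-quality index in
    [0, 1]; when omitted, full quality (SQ = 1) is assumed.

    Initialisation: x_0 = the first outlier-screened observation, P_0 = R0.
    """
    config = config or RAKFConfig()
    zs = [float(getattr(o, "z", o)) for o in observations]
    if not zs:
        return []
    if sq_per_obs is None:
        sqs = [1.0] * len(zs)
    else:
        sqs = [float(s) for s in sq_per_obs]
        if len(sqs) != len(zs):
            raise ConfigError("sq_per_obs length must match observations")

    history: deque = deque(maxlen=config.outlier_window)
    out: list[tuple[KalmanState, StepTrace]] = []
    state: KalmanState | None = None
    for i, (z_raw, sq) in enumerate(zip(zs, sqs)):
        z_used, replaced = correct_outlier(z_raw, history, config)
        # history keeps the RAW observations: storing corrected values would
        # freeze the reference median during a long artifact and permanently
        # latch the gate shut once the true rate drifts away from it
        history.append(z_raw)
        weight = max(config.alpha, sq) if config.use_weighting else 1.0
        if state is None:
            state = KalmanState(x_hat=z_used, p=config.r0, k=0)
            trace = StepTrace(
                k=0, z_raw=z_raw, z_used=z_used, outlier_replaced=replaced,
                x_prior=z_used, p_prior=config.r0, residual=0.0,
                r_adaptive=config.r0, gain=0.0, weight=weight,
                x_hat=state.x_hat, p=state.p,
            )
            out.append((state, trace))
            continue
        state, trace = update(state, z_used, weight, config)
        trace.z_raw = z_raw
        trace.outlier_replaced = replaced
        out.append((state, trace))
    return out


def steps_to_frame(steps) -> "pd.DataFrame":  # noqa: F821
    """Step traces as a DataFrame (k, z_raw, z_used, x_prior, residual, ...)."""
    import pandas as pd

    rows = [t.__dict__ for _, t in steps]
    return pd.DataFrame(rows)


def reference_kalman(observations, x0: float, p0: float, q: float, r: float) -> np.ndarray:
    """Textbook scalar Kalman filter (constant R, no weighting, no outliers).

    Kept as an independent reference for validating the RAKF reduction: with
    w == 1, beta -> infinity and outlier handling off, the RAKF must coincide
    with this recursion.
    """
    zs = np.asarray(observations, dtype=float)
    x, p = float(x0), float(p0)
    out = np.empty_like(zs)
    for i, z in enumerate(zs):
        p_prior = p + q
        k_gain = p_prior / (p_prior + r)
        x = x + k_gain * (z - x)
        p = (1.0 - k_gain) * p_prior
        out[i] = x
    return out
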