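"""Ground-truthed synthetic rPPG traces and videos.

The generator is the single source of ground truth for all end-to-end tests:
it emulates a quasi-sinusoidal pulsatile component (fundamental plus 30%
first harmonic, to keep peak detection honest) riding on low-frequency
baseline wander (illumination drift / slow head motion), broadband Gaussian
sensor noise, sparse large-amplitude motion-artifact bursts (boxcar-windowed
low-frequency transients), and a multiplicative skin-reflectance gain that
mimics melanin-dependent pulse amplitude.

Default study conditions (60 s at 30 fps, pulse amplitude 1, drift amplitude
1.8 at 0.1 Hz, noise sigma 0.7, bursts at 5x pulse amplitude) put the raw
cardiac-band SNR near -5 dB, i.e. a drift/noise-dominated trace of the kind
the pipeline is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .acquisition import FrameSequence, RawTrace
from .errors import ConfigError

HRTrajectory = Callable[[np.ndarray], np.ndarray]


def constant_hr(bpm: float) -> HRTrajectory:
    """Constant heart rate."""
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(bpm))


def ramp_hr(start_bpm: float, end_bpm: float, duration: float) -> HRTrajectory:
    """Linear ramp from start to end over ``duration`` seconds."""
    def traj(t):
        t = np.asarray(t, dtype=float)
        return start_bpm + (end_bpm - start_bpm) * np.clip(t / duration, 0.0, 1.0)
    return traj


def modulated_hr(mean_bpm: float, amp_bpm: float, freq_hz: float = 0.05) -> HRTrajectory:
    """Sinusoidally modulated heart rate (slow respiratory-style variation)."""
    def traj(t):
        t = np.asarray(t, dtype=float)
        return mean_bpm + amp_bpm * np.sin(2.0 * np.pi * freq_hz * t)
    return traj


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic recording."""

    duration: float = 60.0
    fps: float = 30.0
    hr_trajectory: HRTrajectory = None  # defaults to constant 72 bpm
    pulse_amplitude: float = 1.0
    harmonic_ratio: float = 0.3
    baseline_level: float = 128.0
    drift_amplitude: float = 1.8
    drift_freq: float = 0.1  # Hz, <= 0.3
    noise_sigma: float = 0.7
    artifact_bursts: tuple = ()  # iterable of (t_start, duration, amplitude)
    reflectance_gain: float = 1.0  # (0, 1], skin-tone-dependent amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_trajectory is None:
            self.hr_trajectory = constant_hr(72.0)
        if self.duration <= 0 or self.fps <= 0:
            raise ConfigError("duration and fps must be positive")
        if not 0.0 < self.reflectance_gain <= 1.0:
            raise ConfigError("reflectance_gain must be in (0, 1]")
        if self.drift_freq > 0.3:
            raise ConfigError("baseline drift frequency must be <= 0.3 Hz")
        t = np.arange(int(round(self.duration * self.fps))) / self.fps
        hr = np.asarray(self.hr_trajectory(t), dtype=float)
        if hr.min() < 45.0 or hr.max() > 150.0:
            raise ConfigError("hr_trajectory must stay within [45, 150] bpm")


def default_bursts(duration: float, amplitude: float = 5.0) -> tuple:
    """Two motion-artifact bursts at 1/3 and 2/3 of the recording, 2 s each."""
    return ((duration / 3.0, 2.0, amplitude), (2.0 * duration / 3.0, 2.0, amplitude))


def _components(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    n = int(round(spec.duration * spec.fps))
    t = np.arange(n) / spec.fps
    rng = np.random.default_rng(spec.seed)
    hr = np.asarray(spec.hr_trajectory(t), dtype=float)
    # instantaneous phase from the HR trajectory
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / spec.fps
    amp = spec.reflectance_gain * spec.pulse_amplitude
    pulse = amp * (np.sin(phase) + spec.harmonic_ratio * np.sin(2.0 * phase))
    drift = spec.drift_amplitude * np.sin(2.0 * np.pi * spec.drift_freq * t + 0.7)
    noise = rng.normal(0.0, spec.noise_sigma, n)
    bursts = np.zeros(n)
    for (t_start, dur, b_amp) in spec.artifact_bursts:
        mask = (t >= t_start) & (t < t_start + dur)
        m = int(mask.sum())
        if m == 0:
            continue
        # boxcar-windowed broadband low-frequency transient: head motion has
        # spectral content reaching into the cardiac band, so bursts corrupt
        # the windowed spectral observations, not just the baseline
        from scipy.signal import butter, sosfiltfilt

        raw_burst = rng.normal(0.0, 1.0, max(m, 64))
        sos = butter(2, min(1.5, 0.45 * spec.fps), btype="lowpass", fs=spec.fps, output="sos")
        shaped = sosfiltfilt(sos, raw_burst)[:m]
        rms = float(np.sqrt(np.mean(shaped ** 2)))
        if rms > 0:
            bursts[mask] += b_amp * shaped / rms
    return {"t": t, "hr": hr, "pulse": pulse, "drift": drift, "noise": noise, "bursts": bursts}


def generate_trace(spec: SyntheticSpec) -> tuple[RawTrace, np.ndarray]:
    """Synthesize a raw trace; returns (RawTrace, per-frame ground-truth HR in bpm).

    The green channel carries the full pulsatile component; red and blue get
    attenuated copies (0.5x and 0.3x) with independent sensor noise, all
    sharing the same drift and artifact bursts.
    """
    c = _components(spec)
    rng = np.random.default_rng(spec.seed + 1)
    common = spec.baseline_level + c["drift"] + c["bursts"]
    channels = {
        "g": common + c["pulse"] + c["noise"],
        "r": common + 0.5 * c["pulse"] + rng.normal(0.0, spec.noise_sigma, len(c["t"])),
        "b": common + 0.3 * c["pulse"] + rng.normal(0.0, spec.noise_sigma, len(c["t"])),
    }
    trace = RawTrace(
        time=c["t"],
        channels=channels,
        fps=spec.fps,
        n_pixels_used=np.full(len(c["t"]), 1, dtype=int),
    )
    return trace, c["hr"]


def generate_video(
    spec: SyntheticSpec,
    frame_size: tuple[int, int] = (64, 64),
) -> tuple[FrameSequence, tuple, np.ndarray]:
    """Synthesize a frame sequence with an embedded 'face' patch.

    Returns ``(sequence, face_box, ground_truth_hr)``. The patch interior
    follows the generated per-channel trace (float frames in [0, 1], the
    trace's 0-255 scale divided by 255); the background is dark so the
    default :class:`~rppgkit.acquisition.BrightPatchDetector` finds the patch.
    """
    h, w = frame_size
    if h < 64 or w < 64:
        raise ConfigError("frame size must be at least 64x64")
    trace, hr = generate_trace(spec)
    n = len(trace)
    # face patch occupies the central half of the frame
    box = (w // 4, h // 4, w // 2, h // 2)
    frames = np.full((n, h, w, 3), 0.08, dtype=np.float32)
    x, y, bw, bh = box
    for i in range(n):
        for ci, cname in enumerate("rgb"):
            frames[i, y : y + bh, x : x + bw, ci] = trace.channels[cname][i] / 255.0
    seq = FrameSequence(frames=frames, fps=spec.fps, timestamps=trace.time.copy())
    return seq, box, hr
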