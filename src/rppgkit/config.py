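"""Pipeline-wide configuration: every stage parameter in one flat object.

Defaults follow the published operating point: R0 = 25 bpm^2, process noise
2e-4 (Hz^2/step, i.e. 0.72 bpm^2/step; see :mod:`rppgkit.rakf`), quality
weights lambda = (0.3, 0.4, 0.3), wide band 0.6-3.5 Hz, narrow band
0.8-2.5 Hz, HR search range 45-150 bpm. ``validate_config`` reports every
violated invariant by name instead of raising.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .quality import DEFAULT_LAMBDAS
from .rakf import DEFAULT_Q_BPM2


@dataclass
class PipelineConfig:
    # acquisition
    channel: str = "g"
    redetect_every: int = 30
    roi_grid: int = 2
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple = (8, 8)
    # wavelet
    wavelet_family: str = "db4"
    wavelet_level: int | None = None  # None -> auto from fps
    # bandpass
    wide_band: tuple = (0.6, 3.5)
    narrow_band: tuple = (0.8, 2.5)
    filter_order: int = 4
    # spectral observations
    window_length: float = 10.0
    hop: float = 1.0
    search_band: tuple = (0.75, 2.5)
    # quality
    lambdas: tuple = DEFAULT_LAMBDAS
    # RAKF
    r0: float = 25.0
    q: float = DEFAULT_Q_BPM2
    beta: float = 10.0
    alpha: float = 0.3
    outlier_window: int = 11
    outlier_c: float = 3.0
    t_out_floor: float = 5.0
    # HR estimation
    hr_band_bpm: tuple = (45.0, 150.0)
    prominence_factor: float = 0.3
    # orchestration
    variant: str = "full"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in fields}
        for key in ("wide_band", "narrow_band", "search_band", "lambdas", "hr_band_bpm", "clahe_tile_grid"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every invariant; returns a list of violation messages (empty = ok)."""
    from .evaluation import ABLATION_VARIANTS

    v: list[str] = []
    if config.channel not in ("r", "g", "b"):
        v.append(f"channel must be r/g/b, got {config.channel!r}")
    if config.redetect_every < 1:
        v.append("redetect_every must be >= 1")
    if config.roi_grid < 1:
        v.append("roi_grid must be >= 1")
    if config.wavelet_level is not None and config.wavelet_level < 1:
        v.append("wavelet_level must be >= 1")
    for name, band in (("wide_band", config.wide_band), ("narrow_band", config.narrow_band), ("search_band", config.search_band)):
        if not (0 < band[0] < band[1]):
            v.append(f"{name}: need 0 < f_L < f_H, got {band}")
    if not (config.wide_band[0] <= config.narrow_band[0] and config.narrow_band[1] <= config.wide_band[1]):
        v.append(f"narrow_band {config.narrow_band} must nest inside wide_band {config.wide_band}")
    if config.filter_order < 1:
        v.append("filter_order must be >= 1")
    if config.window_length <= 0 or config.hop <= 0:
        v.append("window_length and hop must be positive")
    if abs(sum(config.lambdas) - 1.0) > 1e-9:
        v.append(f"quality weights lambdas must sum to 1 (normalisation constraint), got {sum(config.lambdas)}")
    if any(l < 0 for l in config.lambdas):
        v.append("quality weights lambdas must be non-negative")
    if config.r0 <= 0:
        v.append("r0 must be positive")
    if config.q <= 0:
        v.append("q must be positive")
    if config.beta <= 0:
        v.append("beta must be positive")
    if not 0.0 < config.alpha <= 1.0:
        v.append(f"alpha must be in (0, 1], got {config.alpha}")
    if config.outlier_window < 1:
        v.append("outlier_window must be >= 1")
    if config.outlier_c <= 0:
        v.append("outlier_c must be positive")
    if config.t_out_floor < 0:
        v.append("t_out_floor must be >= 0")
    if not (0 < config.hr_band_bpm[0] < config.hr_band_bpm[1]):
        v.append(f"hr_band_bpm invalid: {config.hr_band_bpm}")
    if config.prominence_factor <= 0:
        v.append("prominence_factor must be positive")
    if config.variant not in ABLATION_VARIANTS:
        v.append(f"unknown variant {config.variant!r}")
    return v
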