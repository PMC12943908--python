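"""Run configuration: one YAML-backed object covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mekf import FilterConfig
from .preprocess import WaveletConfig
from .seqmodel import LstmConfig
from .synthgait import SyntheticGaitConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Nested settings for the whole pipeline; round-trips through YAML."""

    axis: str = "az"
    one_based_events: bool = False
    scale: float = 1.0
    smoother: bool = True
    seed: int = 0
    log_level: str = "INFO"
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    simulate: SyntheticGaitConfig | None = None
    lstm: LstmConfig = field(default_factory=LstmConfig)
    population_sd: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        # numpy arrays → lists for YAML
        for key in ("Q", "x0", "P0"):
            d["filter"][key] = np.asarray(d["filter"][key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "wavelet" in d and isinstance(d["wavelet"], dict):
            d["wavelet"] = WaveletConfig(**d["wavelet"])
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterConfig(**d["filter"])
        if d.get("simulate") is not None and isinstance(d["simulate"], dict):
            d["simulate"] = SyntheticGaitConfig(**d["simulate"])
        if "lstm" in d and isinstance(d["lstm"], dict):
            d["lstm"] = LstmConfig(**d["lstm"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
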