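"""Pipeline configuration: one block per stage, loadable from YAML/JSON.

Defaults reproduce the study protocol: second-order form removal, spline
filter with a 0.025 mm nesting index, ISO-default functional thresholds
(s = 0.2, p = 10%, q = 80%, 5% summit pruning), FDR 0.05, and six-record
subsampling repeated ten times.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .preprocess import PreprocessConfig
from .stats_pipeline import StatsConfig

__all__ = ["IsoConfig", "PipelineConfig", "load_config"]


@dataclass
class IsoConfig:
    """Settings of the texture-parameter stage."""

    acf_threshold: float = 0.2      # Sal/Str decay threshold s
    volume_p: float = 10.0          # material-ratio bound p, %
    volume_q: float = 80.0          # material-ratio bound q, %
    summit_pruning_pct: float = 5.0  # prominence gate, % of Sz


@dataclass
class PipelineConfig:
    """All stage settings plus the run seed."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    iso: IsoConfig = field(default_factory=IsoConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(dc_type, data: dict):
    names = {f.name for f in dataclasses.fields(dc_type)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(
            f"unknown {dc_type.__name__} settings: {sorted(unknown)}")
    return dc_type(**data)


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file (None = defaults)."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text)) or {}
    cfg = PipelineConfig(seed=int(data.get("seed", 0)))
    if "preprocess" in data:
        cfg.preprocess = _build(PreprocessConfig, data["preprocess"])
    if "iso" in data:
        cfg.iso = _build(IsoConfig, data["iso"])
    if "stats" in data:
        cfg.stats = _build(StatsConfig, data["stats"])
    return cfg
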