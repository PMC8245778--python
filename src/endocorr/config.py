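"""Pipeline configuration: flat keys, loadable from YAML or JSON."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .enrichment import DEFAULT_MARKERS
from .errors import ConfigError


@dataclass
class PipelineConfig:
    expression: str = ""
    segmentation: str = ""
    clinical: str = ""
    marker_ids: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    method: str = "spearman"
    enrichment_threshold: float = 0.3
    extremes_k: int = 20
    up_threshold: float = 0.1
    down_threshold: float = -0.4
    age_cutoff: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ConfigError(f"unknown correlation method {self.method!r}")
        if not (-1.0 < self.enrichment_threshold < 1.0):
            raise ConfigError("enrichment_threshold must lie in (-1, 1)")
        if self.extremes_k < 1:
            raise ConfigError("extremes_k must be positive")
        if not self.down_threshold < self.up_threshold:
            raise ConfigError("down_threshold must be below up_threshold")
        if len(self.marker_ids) < 2:
            raise ConfigError("need at least 2 marker ids")

    def require_inputs(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"config is missing the {name} input path")
            if not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a flat YAML/JSON mapping into a PipelineConfig."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    return PipelineConfig(**raw)
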