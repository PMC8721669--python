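"""Analysis configuration: every tunable threshold of the pipeline.

Defaults follow the study conventions where stated (250 µm margin, 30 tiles,
pseudo-count 0.01 cells/mm², k tested over 1..10 with 300 Lloyd iterations);
unstated thresholds (CD8 cutoffs, TLS detector parameters, superficial depth)
carry documented defaults and are always echoed into outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    # region geometry
    margin_width_um: float = 250.0
    n_tiles: int = 30
    tile_edge_um: float = 500.0
    # immune-phenotype calling (cells/mm²)
    cd8_tumor_high: float = 50.0
    cd8_stroma_high: float = 50.0
    use_margin_for_excluded: bool = True
    # TLS composition clustering
    pseudo_count: float = 0.01
    k_range: tuple[int, ...] = tuple(range(1, 11))
    kmeans_max_iter: int = 300
    kmeans_n_init: int = 10
    seed: int = 0
    # TLS detection
    link_radius_um: float = 30.0
    min_lymphocytes: int = 50
    min_b_fraction: float = 0.3
    # depth stratification & maturation
    superficial_depth_um: float = 1000.0
    min_cd21: int = 5
    min_cd23: int = 5

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        self.validate()

    def validate(self) -> "AnalysisConfig":
        for name in ("margin_width_um", "tile_edge_um", "link_radius_um",
                     "superficial_depth_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.pseudo_count <= 0:
            raise ConfigError("pseudo_count must be > 0")
        if self.cd8_tumor_high < 0 or self.cd8_stroma_high < 0:
            raise ConfigError("CD8 thresholds must be >= 0")
        if not self.k_range:
            raise ConfigError("k_range must be nonempty")
        if any(b <= a for a, b in zip(self.k_range, self.k_range[1:])):
            raise ConfigError("k_range must be strictly ascending")
        if self.n_tiles < 1 or self.min_lymphocytes < 1:
            raise ConfigError("counts must be >= 1")
        if not 0 <= self.min_b_fraction <= 1:
            raise ConfigError("min_b_fraction must be in [0, 1]")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a flat key/value mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the configuration, logged with every artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
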