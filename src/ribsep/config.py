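"""Run configuration: every tunable of the pipeline in one YAML-backed record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from ribsep.pca_bss import BSSConfig
from ribsep.phantom import PhantomConfig
from ribsep.reconstruction import SuppressionConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # edge targets
    sigma: float = 5.0
    threshold: float = 0.8
    combine_policy: str = "union"
    highpass_window: int = 90
    highpass_eps: float = 0.023
    # edge list extraction
    gap_tol: float = 10.0
    angle_tol_deg: float = 30.0
    # profile sampling / BSS / reconstruction
    n_outer: int = 10
    n_inner: int = 40
    max_dist: float = 100.0
    margin: int = 3
    smooth_scale: int = 1000
    var_threshold: float = 0.95
    smooth_kernel: int = 30
    edge_kernel: int = 10
    edge_each_side: int = 10
    edge_margin: int = 5
    reprocess: str = "edges"
    # io / training
    image_size: int = 512
    batch_size: int = 6
    epochs: int = 300
    lr0: float = 1e-4
    base_channels: int = 8
    seed: int = 0
    # phantom generation
    phantom: dict = field(default_factory=dict)

    def suppression(self) -> SuppressionConfig:
        return SuppressionConfig(
            n_outer=self.n_outer,
            n_inner=self.n_inner,
            max_dist=self.max_dist,
            bss=BSSConfig(
                smooth_scale=self.smooth_scale,
                margin=self.margin,
                var_threshold=self.var_threshold,
                smooth_kernel=self.smooth_kernel,
                seed=self.seed,
            ),
            edge_each_side=self.edge_each_side,
            edge_kernel=self.edge_kernel,
            edge_margin=self.edge_margin,
            reprocess=self.reprocess,
        )

    def phantom_config(self) -> PhantomConfig:
        kwargs = dict(self.phantom)
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        kwargs.setdefault("seed", self.seed)
        return PhantomConfig(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
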