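"""Pipeline configuration with study defaults and lossless YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    rarefaction_depth: int = 4930
    prevalence_threshold: float = 0.20
    stage1_subsets: int = 90
    stage2_subsets: int = 300
    n_trees: int = 700
    panel_size: int = 50
    train_fraction: float = 0.8
    vote_threshold: float = 0.5
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if not 0 <= self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must be in [0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("stage1_subsets", "stage2_subsets", "n_trees", "panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short provenance hash of the canonical config."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
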