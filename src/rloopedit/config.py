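"""Declarative pipeline configuration with schema validation.

A single YAML file holds every stage parameter; unknown keys are rejected
and the fully resolved configuration is echoed into each run directory so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "rloopedit_run"
    # stage parameters (defaults are the analysis cut-offs used throughout)
    d_proximity: int = 1500
    d_cluster: int = 1000
    n_perm: int = 200
    g4_threshold: float = 1.2
    g4_window: int = 25
    g4_density_bin: int = 100
    gcskew_window: int = 200
    snv_flank: int = 200
    profile_flank: int = 2000
    fdr: float = 0.05
    fc: float = 1.5
    top_fraction: float | None = 0.25
    merge_within: int = 1000
    min_recurrence: int = 2
    nmf_rank: int = 2
    nmf_restarts: int = 20
    rloop_strand_means: str = "displaced"
    n_random_sites: int = 20000
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = _build_synthetic(self.synthetic)
        for name in ("d_proximity", "d_cluster", "g4_window", "g4_density_bin",
                     "gcskew_window", "snv_flank", "profile_flank", "merge_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.g4_window < 1 or self.gcskew_window < 1:
            raise ValueError("window sizes must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.fc < 1:
            raise ValueError("fc must be >= 1")
        if self.rloop_strand_means not in ("displaced", "hybrid"):
            raise ValueError("rloop_strand_means must be 'displaced' or 'hybrid'")
        if self.profile_flank % self.gcskew_window:
            raise ValueError("profile_flank must be a multiple of gcskew_window")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["synthetic"]["contigs"] = [list(c) for c in data["synthetic"]["contigs"]]
        data["synthetic"]["rloop_length"] = list(data["synthetic"]["rloop_length"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _build_synthetic(data: dict) -> SyntheticConfig:
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown synthetic configuration keys: {sorted(unknown)}")
    data = dict(data)
    if "contigs" in data:
        data["contigs"] = [tuple(c) for c in data["contigs"]]
    if "rloop_length" in data:
        data["rloop_length"] = tuple(data["rloop_length"])
    return SyntheticConfig(**data)
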