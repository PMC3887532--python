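"""Declarative pipeline configuration and seeded reproducibility helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core import PanelError
from .simulate import SimConfig


@dataclass
class Thresholds:
    p_value: float = 0.001
    fdr_q: float = 0.20
    maf_min: float = 0.05
    top_fst_quantile: float = 0.99
    maf_bins: int = 20
    low_freq_syn: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_value", "fdr_q", "maf_min", "low_freq_syn"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise PanelError(f"threshold {name}={v} outside (0, 1]")
        if not (0.0 < self.top_fst_quantile < 1.0):
            raise PanelError("top_fst_quantile must lie in (0, 1)")
        if self.maf_bins < 1:
            raise PanelError("maf_bins must be >= 1")
        if self.maf_min > 0.5:
            raise PanelError("maf_min cannot exceed 0.5")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs: paths, thresholds, trait rules,
    testers, the simulation block and the global seed."""

    workdir: str = "out"
    paths: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    bph_min_traits: list[str] = field(default_factory=lambda: [
        "days_to_anthesis", "tassel_branch_count", "tassel_angle",
        "upper_leaf_angle"])
    testers: list[str] = field(default_factory=list)
    sfs_bins: int = 20
    window_bp: int = 1_000_000
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise PanelError(f"unknown config keys {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def path(self, key: str, default_name: str | None = None) -> Path:
        """Resolve a configured path, defaulting into the workdir."""
        if key in self.paths:
            return Path(self.paths[key])
        if default_name is None:
            raise PanelError(f"config has no path for {key!r}")
        return Path(self.workdir) / default_name


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (independent of execution order)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


def write_manifest(path: str | Path, stage: str, seed: int, child_seed: int,
                   inputs: dict, thresholds: Thresholds,
                   outputs: dict) -> None:
    manifest = {"stage": stage, "seed": seed, "stage_seed": child_seed,
                "inputs": inputs, "thresholds": asdict(thresholds),
                "outputs": outputs}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
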