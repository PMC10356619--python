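"""Run configuration for the analysis pipeline.

All window sizes, cluster counts, thresholds and permutation counts used by
the pipeline live in :class:`AnalysisConfig`.  The defaults are the values
used throughout the downstream modules: 10-cell windows overclustered to 30
for multicellular neighbourhoods, 100- and 300-cell windows with 20 clusters
for communities and tissue units, 5 same-type neighbours for the density
score, an 85% cumulative-fraction rule for spatial-context combinations with
a 0.1% plotting frequency floor, a 15% contribution threshold for hierarchy
edges, a 5-instance floor for motif testing, and 1,000 / 10,000 permutations
for the motif and ligand-receptor permutation tests respectively.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    k_window_nbhd: int = 10
    k_window_comm: int = 100
    k_window_tissue: int = 300
    n_clusters_nbhd: int = 30
    n_clusters_comm: int = 20
    k_density: int = 5
    k_clq: int = 10
    context_threshold: float = 0.85
    context_min_freq: float = 0.001
    hierarchy_threshold: float = 0.15
    motif_min_instances: int = 5
    n_permutations: int = 1000
    lr_n_permutations: int = 10000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            "k_window_nbhd", "k_window_comm", "k_window_tissue",
            "n_clusters_nbhd", "n_clusters_comm", "k_density", "k_clq",
            "motif_min_instances", "n_permutations", "lr_n_permutations",
        )
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        fractions = (
            "context_threshold", "context_min_freq", "hierarchy_threshold",
            "alpha",
        )
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 < float(v) < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def hash(self) -> str:
        """Stable hex digest of the configuration (used in output manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a JSON or YAML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
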