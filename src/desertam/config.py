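"""Pipeline configuration: one flat-key YAML file drives every stage.

A single global seed deterministically derives per-stage seeds (stage-name
hashing), so a stage rerun standalone reproduces its part of a full run.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "out"
    # read processing
    fwd_primer: str = "CAGCCGCGGTAATTCCAGCT"
    rev_primer: str = "GAACCCAAACACTTTGGTTTCC"
    max_mismatch: int = 1
    min_mean_q: float = 30.0
    min_overlap: int = 10
    max_overlap: int = 300
    min_identity: float = 0.75
    # VT assignment
    id_threshold: float = 0.97
    cov_threshold: float = 0.95
    prescreen_top: int = 3
    # diversity
    bootstrap_B: int = 200
    # null models
    n_reps: int = 999
    z_crit: float = 1.96
    # ordination
    axes: int = 2
    nmds_starts: int = 4
    n_perm: int = 999
    # orchestration
    seed: int = 0
    skip_reads: bool = False

    _BOUNDS = {
        "max_mismatch": (0, 10), "min_mean_q": (0, 41),
        "min_overlap": (1, 1000), "max_overlap": (1, 1000),
        "min_identity": (0.0, 1.0), "id_threshold": (0.0, 1.0),
        "cov_threshold": (0.0, 1.0), "prescreen_top": (1, 10_000),
        "bootstrap_B": (50, 100_000), "n_reps": (1, 10 ** 7),
        "z_crit": (0.0, 100.0), "axes": (1, 10), "nmds_starts": (1, 1000),
        "n_perm": (1, 10 ** 7),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_overlap > self.max_overlap:
            raise ValueError("min_overlap > max_overlap")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF
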