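"""Pipeline configuration with lossless YAML round-tripping.

A single structured config drives the end-to-end run; every stochastic
stage has an explicit seed (derived deterministically from the master seed
when not set). Defaults mirror the study parameters: participant QC at
mean r >= 0.7, seed presence > 85%, top-100 axis genes, 10,000 spin and
1,000 variogram permutations, alpha = 0.05.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

ALL_STAGES = (
    "simulate",
    "prepare",
    "decompose",
    "stability",
    "nulls",
    "genes",
    "maps",
    "enrich",
    "xspecies",
    "trajectories",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # synthetic-data overrides (field name -> value on SyntheticConfig)
    synthetic: dict = field(default_factory=dict)
    # QC
    participant_r_threshold: float = 0.7
    seed_presence_fraction: float = 0.85
    # decomposition
    k: int = 10
    # nulls
    n_spin: int = 10_000
    n_variogram: int = 1_000
    # gene selection / enrichment
    alpha: float = 0.05
    top_k: int = 100
    # stability
    bootstrap_B: int = 100
    run_loocv: bool = False
    # per-stage seeds; None -> derived from the master seed
    seed_simulate: int | None = None
    seed_nulls: int | None = None
    seed_spin: int | None = None
    seed_bootstrap: int | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def resolved_seeds(self) -> dict[str, int]:
        """Explicit per-stage seeds (< 2**31), derived from the master seed
        where not set."""
        ss = np.random.SeedSequence(self.seed)
        derived = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
        return {
            "simulate": self.seed_simulate if self.seed_simulate is not None else derived[0],
            "nulls": self.seed_nulls if self.seed_nulls is not None else derived[1],
            "spin": self.seed_spin if self.seed_spin is not None else derived[2],
            "bootstrap": self.seed_bootstrap if self.seed_bootstrap is not None else derived[3],
        }

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 1 or self.top_k < 1:
            raise ValueError("k and top_k must be >= 1")
        if self.n_spin < 1 or self.n_variogram < 1 or self.bootstrap_B < 1:
            raise ValueError("ensemble sizes must be >= 1")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
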