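"""Run configuration: a flat, schema-versioned YAML file.

Unknown keys are rejected (silent key typos are the dominant failure mode
of config-driven pipelines) and the seed is mandatory: all randomness in a
run flows from it through documented per-stage derived streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from .exceptions import SchemaError, ValidationError

SCHEMA_VERSION = 1

# per-stage seed stream offsets (derived from the root seed)
STAGE_SIMULATE = 0
STAGE_CLASSIFY = 1
STAGE_MDS = 2


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    All numeric fields are positive; ``seed`` has no default on purpose.
    """

    seed: int
    schema_version: int = SCHEMA_VERSION
    fs_hz: int = 1000
    n_flies: int = 20
    n_reps: int = 10
    trial_s: float = 11.0
    bin_s: float = 1.0
    discard_lead_bins: int = 1
    genotype_presets: Optional[str] = None  # path to a preset JSON; None = built-ins
    genotypes: Optional[List[str]] = None   # subset of preset names; None = all
    gamma_grid: List[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(11)]
    )
    n_delta: int = 10
    k_folds: int = 10
    n_iter: int = 1000
    metric: str = "euclidean"
    output_dir: str = "flyvep_out"

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.schema_version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema_version {self.schema_version}; "
                f"this version reads {SCHEMA_VERSION}"
            )
        positive = {
            "fs_hz": self.fs_hz, "n_flies": self.n_flies, "n_reps": self.n_reps,
            "trial_s": self.trial_s, "bin_s": self.bin_s,
            "n_delta": self.n_delta, "k_folds": self.k_folds,
            "n_iter": self.n_iter,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.discard_lead_bins < 0:
            raise ValidationError("discard_lead_bins must be >= 0")
        if self.metric not in ("euclidean", "correlation"):
            raise ValidationError(f"unknown metric {self.metric!r}")

    def stage_seed(self, stage: int) -> int:
        """Derived, documented per-stage seed (< 2**31)."""
        return int(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
            .generate_state(1)[0] % (2**31)
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"config {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise SchemaError(f"unknown config key(s): {unknown}")
        if "seed" not in raw:
            raise ValidationError("seed is mandatory")
        return cls(**raw)
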