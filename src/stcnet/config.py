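"""Run configuration: one object carrying every stage's effective parameters.

Defaults are the method's published settings: confidence threshold 700,
inverse regularization strength 0.1, 10-fold CV, minimum 10 positive drugs
per ADR, top-50 protein evaluation with minimum support 5, and 1000 balanced
negative resamples.  Stage seeds derive from the single global seed via fixed
offsets so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

# per-stage seed offsets added to the global seed
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "embed": 1,
    "train": 2,
    "evaluate": 3,
}


@dataclass
class RunConfig:
    # inputs
    ppi: str | None = None
    drug_target: str | None = None
    drug_adr: str | None = None
    benchmark: str | None = None
    grouping: str | None = None
    # filtering
    threshold: int = 700
    # walks
    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    # skip-gram
    dimensions: int = 128
    window: int = 10
    epochs: int = 5
    negative: int = 5
    # classification / evaluation
    inverse_reg_strength: float = 0.1
    cv_folds: int = 10
    min_drugs: int = 10
    top_k: int = 50
    min_support: int = 5
    n_resamples: int = 1000
    # run
    seed: int = 0
    out_dir: str = "stcnet_out"

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS[stage]

    def out_path(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
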