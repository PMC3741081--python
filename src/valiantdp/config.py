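"""Run configuration shared by the command-line interface."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .multistring import DEFAULT_SIZE_CAP

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Engine and scoring knobs for one invocation.

    Identical config plus inputs yields bit-identical outputs for the
    discrete domains (max-plus on integers, boolean).
    """

    kernel: Optional[str] = None  # None selects each variant's default
    cutoff: int = 32
    verify: bool = False
    seed: int = 0
    size_cap: int = DEFAULT_SIZE_CAP
    log_level: str = "warning"
    # simultaneous-alignment-and-folding scoring constants
    saf_match: float = 1.0
    saf_mismatch: float = -1.0
    saf_gap: float = -2.0
    saf_pair_bonus: float = 2.0
    saf_pair_penalty: float = -3.0

    def __post_init__(self):
        if self.cutoff < 1:
            raise ValueError("cutoff must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
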