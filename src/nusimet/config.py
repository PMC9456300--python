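"""Run configuration for the identification pipeline.

All tunables of a pipeline run live in one validated, serializable record so
that every output can embed the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .chem import HYDROXYL, THIOPHOSPHATE, MassKind
from .fragments import DEFAULT_TERMINAL_POLICY

__all__ = ["RunConfig"]

_TERMINAL_CODES = {HYDROXYL: "OH", THIOPHOSPHATE: "SP"}
_TERMINAL_FROM_CODE = {v: k for k, v in _TERMINAL_CODES.items()}


@dataclass(frozen=True)
class RunConfig:
    """Candidate-space, tolerance and I/O parameters of one pipeline run.

    Defaults: candidate lengths 2-4 (the observed metabolite length range),
    all four terminal combinations, at most one base loss; ion pairing at
    0.2 Da / 0.1 min; candidate matching against monoisotopic masses at a
    deliberately loose 2.5 Da (configurable down to ppm-scale for
    high-accuracy data).
    """

    min_len: int = 2
    max_len: int = 4
    terminal_policy: tuple[tuple[str, str], ...] = DEFAULT_TERMINAL_POLICY
    max_base_losses: int = 1
    pair_mass_tol: float = 0.2  # Da
    pair_rt_tol: float = 0.1  # min
    match_tol: float = 2.5  # Da
    mass_kind: str = MassKind.MONOISOTOPIC.value
    seed: int | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.max_base_losses < 0:
            raise ValueError("max_base_losses must be >= 0")
        if self.pair_mass_tol <= 0 or self.pair_rt_tol <= 0 or self.match_tol <= 0:
            raise ValueError("tolerances must be positive")
        MassKind(self.mass_kind)  # raises on unknown kind
        if not self.terminal_policy:
            raise ValueError("terminal policy must be non-empty")

    # Serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        record = asdict(self)
        record["terminal_policy"] = [
            "-".join(_TERMINAL_CODES[t] for t in combo) for combo in self.terminal_policy
        ]
        return record

    @classmethod
    def from_dict(cls, record: dict) -> "RunConfig":
        record = dict(record)
        policy = record.get("terminal_policy")
        if policy is not None:
            record["terminal_policy"] = tuple(
                tuple(_TERMINAL_FROM_CODE[code] for code in combo.split("-"))
                for combo in policy
            )
        return cls(**record)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            record = yaml.safe_load(handle) or {}
        return cls.from_dict(record)

    def digest(self) -> str:
        """Short stable hash of the configuration, echoed into run logs."""
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:12]
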