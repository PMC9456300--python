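"""File I/O: peak-list CSV reading, TSV output writing, run logging.

Peak lists are CSV with header ``mz,z,rt,intensity`` (charge sign is ignored;
a blank charge is read as 1 and flagged unknown).  Outputs are UTF-8 TSV with
a ``#``-prefixed header block echoing the configuration snapshot, so a result
file is self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .identify import Assignment, AssignmentTable
from .spectra import ObservedIon

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "write_assignment_table",
    "read_assignment_table",
    "write_summary",
    "log_run",
]

logger = logging.getLogger("nusimet")

_REQUIRED_COLUMNS = ("mz", "z", "rt", "intensity")


def read_peaklist(path: str | Path) -> list[ObservedIon]:
    """Read a centroided peak list CSV into observed ions.

    Errors name the offending column or the file:line of a bad value.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    ions = []
    for index, row in frame.iterrows():
        line = int(index) + 2  # header is line 1
        try:
            charge_known = pd.notna(row["z"])
            z = abs(int(row["z"])) if charge_known else 1
            ion = ObservedIon(
                mz=float(row["mz"]),
                z=z,
                rt=float(row["rt"]),
                intensity=float(row["intensity"]),
                charge_known=bool(charge_known),
            )
        except (TypeError, ValueError) as error:
            raise ValueError(f"{path}:{line}: invalid ion row: {error}") from None
        ions.append(ion)
    return ions


def write_peaklist(ions, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "mz": [ion.mz for ion in ions],
            "z": [ion.z for ion in ions],
            "rt": [ion.rt for ion in ions],
            "intensity": [ion.intensity for ion in ions],
        }
    )
    frame.to_csv(path, index=False)


def _config_header(config: RunConfig) -> str:
    lines = [f"# config_hash: {config.digest()}"]
    for line in config.to_yaml().strip().splitlines():
        lines.append(f"# config: {line}")
    return "\n".join(lines) + "\n"


def _assignment_row(assignment: Assignment) -> dict:
    species = assignment.species
    candidate_list = ";".join(
        f"{candidate.sequence}|{candidate.label.render()}|{delta:+.4f}"
        for candidate, delta in assignment.candidates
    )
    return {
        "rt": round(species.rt, 4),
        "mass": round(species.mass, 4),
        "ions": ";".join(f"{ion.mz:.4f}" for ion in species.ions),
        "charges": ";".join(str(ion.z) for ion in species.ions),
        "status": assignment.status,
        "coeluting": assignment.coeluting,
        "n_candidates": len(assignment.candidates),
        "n_formula_groups": assignment.n_formula_groups,
        "candidates": candidate_list,
    }


def write_assignment_table(table: AssignmentTable, path: str | Path) -> None:
    """Write an assignment table as TSV with a config header block."""
    path = Path(path)
    frame = pd.DataFrame([_assignment_row(a) for a in table])
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(_config_header(table.config))
        frame.to_csv(handle, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    """Read back a written assignment table (config header lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_summary(summary: dict, config: RunConfig, path: str | Path) -> None:
    rows = []
    def _flatten(prefix: str, value) -> None:
        if isinstance(value, dict):
            for key, sub in value.items():
                _flatten(f"{prefix}.{key}" if prefix else str(key), sub)
        elif isinstance(value, (tuple, list)):
            rows.append({"key": prefix, "value": ";".join(str(v) for v in value)})
        else:
            rows.append({"key": prefix, "value": value})

    _flatten("", summary)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(_config_header(config))
        pd.DataFrame(rows).to_csv(handle, sep="\t", index=False)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def log_run(config: RunConfig, inputs: list[Path] = ()) -> None:
    """Log tool version, configuration hash and input checksums."""
    try:
        tool_version = version("nusimet")
    except PackageNotFoundError:
        tool_version = "unknown"
    logger.info("nusimet %s, config %s", tool_version, config.digest())
    for path in inputs:
        path = Path(path)
        logger.info("input %s sha256:%s", path, _file_digest(path))
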