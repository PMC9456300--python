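"""Bundled reference tables from the published nusinersen serum study.

Three small transcriptions ship as package data: the metabolite ion table
(observed -1/-2 ions, retention times, deconvoluted and predicted masses,
reported candidate sequences), the two-patient dose-course EIC area table, and
the extraction-recovery table.  They serve as worked-example inputs and as
regression anchors; known internal inconsistencies of the source tables are
flagged in a ``note`` column and preserved verbatim rather than reconciled.
"""

from __future__ import annotations

import io as _io
from importlib import resources

import pandas as pd

from .quantify import AreaRecord
from .spectra import ObservedIon

__all__ = [
    "metabolite_ion_table",
    "metabolite_ions",
    "dose_course_areas",
    "dose_course_records",
    "recovery_table",
    "reported_mass_range",
]


def _read(name: str) -> pd.DataFrame:
    text = resources.files("nusimet.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(_io.StringIO(text), sep="\t", comment="#")


def metabolite_ion_table() -> pd.DataFrame:
    """The metabolite ion table: one row per reported species."""
    return _read("metabolite_ions.tsv")


def metabolite_ions(intensity: float = 1.0) -> list[ObservedIon]:
    """The ion table flattened to a peak list (one ion per observed m/z).

    The source table reports no intensities, so all ions share a nominal
    intensity; 13 species contribute a -1/-2 pair and 4 a single ion.
    """
    ions = []
    for _, row in metabolite_ion_table().iterrows():
        ions.append(
            ObservedIon(
                mz=float(row["mz1"]), z=int(row["z1"]), rt=float(row["rt"]),
                intensity=intensity,
            )
        )
        if pd.notna(row["mz2"]):
            ions.append(
                ObservedIon(
                    mz=float(row["mz2"]), z=int(row["z2"]), rt=float(row["rt"]),
                    intensity=intensity,
                )
            )
    return ions


def dose_course_areas() -> pd.DataFrame:
    """The dose-course EIC area table as printed (wide layout)."""
    return _read("dose_course_areas.tsv")


def dose_course_records() -> list[AreaRecord]:
    """Dose-course areas as long-format records (undetected cells skipped)."""
    frame = dose_course_areas()
    records = []
    for _, row in frame.iterrows():
        for column in frame.columns:
            if "_" not in column:
                continue
            sample, dose = column.split("_", 1)
            value = row[column]
            if isinstance(value, str):
                value = value.strip()
                if value == "-":
                    continue
                value = float(value)
            if pd.isna(value):
                continue
            records.append(
                AreaRecord(sample=sample, dose=dose, mz=float(row["mz"]), area=float(value))
            )
    return records


def recovery_table() -> pd.DataFrame:
    """Extraction-recovery percentages relative to the LLE reference."""
    return _read("recovery.tsv")


def reported_mass_range(column: str = "predicted_mass") -> tuple[float, float]:
    """Min/max reported metabolite mass over the identified species.

    ``column`` selects the mass variant ("predicted_mass" or
    "deconvoluted_mass"); the unidentified species is excluded.
    """
    frame = metabolite_ion_table()
    identified = frame[frame["metabolite"] != "unidentified"]
    values = identified[column].astype(float)
    return float(values.min()), float(values.max())
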