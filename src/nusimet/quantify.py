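"""EIC areas, recovery percentages and dose-course tables.

Without authentic metabolite standards, quantification is relative: peak areas
of extracted ion chromatograms (EIC) are integrated per ion, extraction
recoveries are expressed as percentages of the areas measured for a reference
extraction, and dose-course tables track per-ion areas across the before/after
samples of each intrathecal dose (BID..AIVD labels).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOSE_LABELS",
    "EICTrace",
    "AreaRecord",
    "RecoveryRecord",
    "integrate_eic",
    "recovery_percent",
    "dose_course_table",
    "render_dose_table",
    "parse_dose_table",
]

#: Before/after sampling labels for the four loading doses, in course order.
DOSE_LABELS = ("BID", "AID", "BIID", "AIID", "BIIID", "AIIID", "BIVD", "AIVD")

_DOSE_PAIRS = (("BID", "AID"), ("BIID", "AIID"), ("BIIID", "AIIID"), ("BIVD", "AIVD"))


@dataclass(frozen=True)
class EICTrace:
    """An extracted ion chromatogram: target m/z, rt grid (min), intensities."""

    mz: float
    rt: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt grid and intensity lengths differ")
        if any(b <= a for a, b in zip(self.rt, self.rt[1:])):
            raise ValueError("rt grid must be strictly increasing")
        if any(v < 0 for v in self.intensity):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class AreaRecord:
    """One EIC peak area for (sample, dose label, ion m/z)."""

    sample: str
    dose: str
    mz: float
    area: float
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.dose not in DOSE_LABELS:
            raise ValueError(f"unknown dose label {self.dose!r}; expected one of {DOSE_LABELS}")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    @property
    def detected(self) -> bool:
        return self.area > self.threshold


@dataclass(frozen=True)
class RecoveryRecord:
    """Recovery of one ion for one extraction method, relative to a reference."""

    method: str
    mz: float
    recovery: float  # percent
    dispersion: float  # percent, sd of method replicates at the reference scale

    def __post_init__(self) -> None:
        if self.recovery < 0 or self.dispersion < 0:
            raise ValueError("recovery and dispersion must be >= 0")


def integrate_eic(trace: EICTrace, window: tuple[float, float]) -> float:
    """Trapezoidal EIC area over an rt window, with boundary interpolation.

    Interpolating the signal at the window edges makes the integral additive
    over disjoint windows and invariant to grid refinement for piecewise-linear
    signals.  An empty overlap yields 0 with a warning.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("window bounds out of order")
    rt = np.asarray(trace.rt, dtype=float)
    intensity = np.asarray(trace.intensity, dtype=float)
    lo_eff = max(lo, rt[0])
    hi_eff = min(hi, rt[-1])
    if hi_eff <= lo_eff:
        warnings.warn(
            f"integration window [{lo}, {hi}] does not overlap the rt grid "
            f"[{rt[0]}, {rt[-1]}]",
            stacklevel=2,
        )
        return 0.0
    inside = (rt > lo_eff) & (rt < hi_eff)
    xs = np.concatenate(([lo_eff], rt[inside], [hi_eff]))
    ys = np.interp(xs, rt, intensity)
    return float(np.trapezoid(ys, xs))


def recovery_percent(
    method_areas: Sequence[float],
    reference_areas: Sequence[float],
    method: str = "",
    mz: float = 0.0,
) -> RecoveryRecord:
    """Recovery = 100 * mean(method)/mean(reference); dispersion = 100 * sd(method)/mean(reference).

    The dispersion is the sample standard deviation of the method replicates
    expressed at the reference scale (the "91 +/- 2 %" convention); it is 0
    for a single replicate.
    """
    if not method_areas or not reference_areas:
        raise ValueError("replicate lists must be non-empty")
    ref_mean = mean(reference_areas)
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    recovery = 100.0 * mean(method_areas) / ref_mean
    sd = stdev(method_areas) if len(method_areas) > 1 else 0.0
    return RecoveryRecord(
        method=method, mz=mz, recovery=recovery, dispersion=100.0 * sd / ref_mean
    )


def dose_course_table(records: Sequence[AreaRecord]) -> pd.DataFrame:
    """Pivot area records into a (sample, ion) x dose-label matrix.

    Cells hold areas (NaN where not detected or not measured); for each
    before/after dose pair with both cells detected, a ``<after>/<before>``
    ratio column is added.  Duplicate (sample, dose, ion) records are an error.
    """
    seen: dict[tuple[str, str, float], AreaRecord] = {}
    duplicates = []
    for record in records:
        key = (record.sample, record.dose, record.mz)
        if key in seen:
            duplicates.append(key)
        seen[key] = record
    if duplicates:
        raise ValueError(f"duplicate (sample, dose, mz) records: {sorted(set(duplicates))}")

    samples = sorted({record.sample for record in records})
    mzs = sorted({record.mz for record in records})
    index = pd.MultiIndex.from_tuples(
        [(sample, mz) for sample in samples for mz in mzs], names=["sample", "mz"]
    )
    table = pd.DataFrame(index=index, columns=list(DOSE_LABELS), dtype=float)
    for record in records:
        if record.detected:
            table.loc[(record.sample, record.mz), record.dose] = record.area
    for before, after in _DOSE_PAIRS:
        table[f"{after}/{before}"] = table[after] / table[before]
    return table


def render_dose_table(table: pd.DataFrame) -> str:
    """TSV rendering of a dose-course matrix with "-" for empty cells."""
    out = table.copy()
    buffer = _io.StringIO()
    out.to_csv(buffer, sep="\t", na_rep="-", float_format="%.10g")
    return buffer.getvalue()


def parse_dose_table(text: str) -> list[AreaRecord]:
    """Parse a rendered dose table back into detected-area records.

    "-" cells parse to no record; ratio columns are ignored.  Together with
    :func:`dose_course_table` this round-trips any duplicate-free set of
    detected records.
    """
    frame = pd.read_csv(_io.StringIO(text), sep="\t", na_values=["-"])
    records = []
    for _, row in frame.iterrows():
        for dose in DOSE_LABELS:
            if dose in frame.columns and pd.notna(row[dose]):
                records.append(
                    AreaRecord(
                        sample=str(row["sample"]),
                        dose=dose,
                        mz=float(row["mz"]),
                        area=float(row[dose]),
                    )
                )
    return records
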