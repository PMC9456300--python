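"""Mass chemistry of modified oligonucleotides.

Nusinersen-class antisense oligonucleotides are built from four
2'-O-methoxyethyl (MOE) ribonucleosides (5-methyluridine ``mU``,
5-methylcytidine ``mC``, adenosine ``A``, guanosine ``G``) joined by
phosphorothioate linkages, optionally carrying a terminal thiophosphate
group.  This module represents such molecules (:class:`ModifiedOligo`),
their elemental compositions (:class:`Formula`) and the isotope data
needed to turn compositions into monoisotopic, average or nominal masses.

Composition bookkeeping is additive:

* each residue contributes its MOE nucleoside formula
  (base + ribose + C3H6O MOE substitution - H2O for the glycosidic bond);
* each internal phosphorothioate bridge contributes H3PO3S - 2 H2O
  (net +P +S +O -H); a phosphodiester bridge contributes H3PO4 - 2 H2O;
* a terminal thiophosphate contributes H3PO3S - H2O (net +H +P +2O +S);
  hydroxyl termini contribute nothing.

Neutral free-acid species are modelled throughout; salt forms and metal
adducts are out of scope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "PROTON_MASS",
    "Formula",
    "IsotopeTable",
    "MassKind",
    "Residue",
    "RESIDUES",
    "ModifiedOligo",
    "PHOSPHOROTHIOATE",
    "PHOSPHODIESTER",
    "HYDROXYL",
    "THIOPHOSPHATE",
    "parse_sequence",
    "formula_of",
    "mass",
    "round_half_away",
    "NUSINERSEN_SEQUENCE",
    "NUSINERSEN",
]

#: Mass of a proton (H+), Da. Used for charge (de)convolution of negative ions.
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class Formula(Mapping):
    """Immutable elemental composition (element symbol -> atom count).

    Supports element-wise addition, subtraction and integer scaling.  Zero
    counts are dropped; negative counts are permitted so that compositions can
    be manipulated as deltas, but a *final* molecular formula is expected to be
    non-negative (see :meth:`is_nonnegative`).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        acc: dict[str, int] = {}
        items = counts.items() if isinstance(counts, Mapping) else counts
        for element, n in items:
            n = int(n)
            if n != 0:
                acc[element] = acc.get(element, 0) + n
                if acc[element] == 0:
                    del acc[element]
        object.__setattr__(self, "_counts", dict(sorted(acc.items())))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a formula string such as ``"C26H38N10O15P2S2"``."""
        pos = 0
        pairs: list[tuple[str, int]] = []
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                break
            element, digits = match.groups()
            pairs.append((element, int(digits) if digits else 1))
            pos = match.end()
        if pos != len(text) or (text and not pairs):
            raise ValueError(f"cannot parse formula string: {text!r}")
        return cls(pairs)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, n in other.items():
            merged[element] = merged.get(element, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, n in other.items():
            merged[element] = merged.get(element, 0) - n
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def is_nonnegative(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def total_atoms(self) -> int:
        return sum(self._counts.values())

    def hill(self) -> str:
        """Hill-order formula string (C, H first when carbon is present)."""
        counts = dict(self._counts)
        parts: list[str] = []
        order: list[str] = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(el for el in counts if el not in order)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})" if self._counts else "Formula()"

    def __str__(self) -> str:
        return self.hill()


WATER = Formula.parse("H2O")
#: Elemental delta of the 2'-O-methoxyethyl substitution relative to ribose.
MOE_DELTA = Formula.parse("C3H6O")
RIBOSE = Formula.parse("C5H10O5")

PHOSPHOROTHIOATE = "phosphorothioate"
PHOSPHODIESTER = "phosphodiester"
HYDROXYL = "hydroxyl"
THIOPHOSPHATE = "thiophosphate"

#: Net composition added by one internal linkage between two nucleosides.
LINKAGE_DELTAS: dict[str, Formula] = {
    # H3PO3S - 2 H2O
    PHOSPHOROTHIOATE: Formula({"H": -1, "O": 1, "P": 1, "S": 1}),
    # H3PO4 - 2 H2O
    PHOSPHODIESTER: Formula({"H": -1, "O": 2, "P": 1}),
}

#: Net composition added by one terminal group.
TERMINAL_DELTAS: dict[str, Formula] = {
    HYDROXYL: Formula(),
    # H3PO3S - H2O
    THIOPHOSPHATE: Formula({"H": 1, "O": 2, "P": 1, "S": 1}),
}


class MassKind(str, enum.Enum):
    """Mass convention: monoisotopic, abundance-weighted average, or nominal."""

    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"
    NOMINAL = "nominal"


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope masses (Da) and relative abundances.

    Invariants enforced at construction: per element, masses strictly
    increasing and abundances summing to 1 within 1e-6.
    """

    elements: Mapping[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for element, isotopes in self.elements.items():
            masses = [m for m, _ in isotopes]
            if sorted(masses) != masses or len(set(masses)) != len(masses):
                raise ValueError(f"isotope masses not strictly increasing for {element}")
            total = sum(a for _, a in isotopes)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"isotope abundances for {element} sum to {total}, expected 1"
                )

    def isotopes(self, element: str) -> tuple[tuple[float, float], ...]:
        try:
            return self.elements[element]
        except KeyError:
            raise ValueError(f"element {element!r} absent from isotope table") from None

    def most_abundant(self, element: str) -> tuple[float, float]:
        return max(self.isotopes(element), key=lambda iso: iso[1])

    def monoisotopic_mass(self, element: str) -> float:
        return self.most_abundant(element)[0]

    def average_mass(self, element: str) -> float:
        return sum(m * a for m, a in self.isotopes(element))

    def nominal_mass(self, element: str) -> int:
        return round(self.most_abundant(element)[0])

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "IsotopeTable":
        """The isotope table shipped as package data (``data/isotopes.tsv``)."""
        text = (
            resources.files("nusimet.data").joinpath("isotopes.tsv").read_text("utf-8")
        )
        table: dict[str, list[tuple[float, float]]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("element"):
                continue
            element, m, a = line.split("\t")
            table.setdefault(element, []).append((float(m), float(a)))
        return IsotopeTable({el: tuple(rows) for el, rows in table.items()})


def mass(
    formula: Formula,
    kind: MassKind | str = MassKind.MONOISOTOPIC,
    table: IsotopeTable | None = None,
) -> float:
    """Mass of a formula in Da under the given convention.

    monoisotopic: sum of most-abundant-isotope masses; average: sum of
    abundance-weighted mean masses; nominal: sum of integer mass numbers of
    the most abundant isotope.
    """
    kind = MassKind(kind)
    table = table or IsotopeTable.default()
    if not formula.is_nonnegative():
        raise ValueError(f"formula has negative counts: {dict(formula)}")
    total = 0.0
    for element, n in formula.items():
        if kind is MassKind.MONOISOTOPIC:
            per_atom: float = table.monoisotopic_mass(element)
        elif kind is MassKind.AVERAGE:
            per_atom = table.average_mass(element)
        else:
            per_atom = table.nominal_mass(element)
        total += n * per_atom
    return total


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention, e.g. 2.345 -> 2.35)."""
    factor = 10**ndigits
    scaled = value * factor
    rounded = int(scaled + (0.5 if scaled >= 0 else -0.5))
    return rounded / factor


# ---------------------------------------------------------------------------
# Residue registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    """A MOE ribonucleoside residue: code, free-base formula, nucleoside formula."""

    code: str
    base_name: str
    base: Formula

    @property
    def nucleoside(self) -> Formula:
        # base + MOE-ribose, minus one water for the glycosidic bond
        return self.base + RIBOSE + MOE_DELTA - WATER

    @property
    def abasic(self) -> Formula:
        """Abasic MOE-ribose left after hydrolytic base loss (nucleoside - base + H2O)."""
        return self.nucleoside - self.base + WATER


@lru_cache(maxsize=1)
def _load_residues() -> dict[str, Residue]:
    text = resources.files("nusimet.data").joinpath("residues.tsv").read_text("utf-8")
    registry: dict[str, Residue] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("code"):
            continue
        code, name, base = line.split("\t")
        registry[code] = Residue(code=code, base_name=name, base=Formula.parse(base))
    return registry


RESIDUES: dict[str, Residue] = _load_residues()

#: Abasic MOE-ribose composition (the "MoeR" unit of metabolite notation).
ABASIC_FORMULA = RIBOSE + MOE_DELTA


# ---------------------------------------------------------------------------
# Oligonucleotide model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModifiedOligo:
    """An ordered MOE oligonucleotide with linkage and terminal chemistry.

    Residues are stored left-to-right exactly as written in the source
    sequence string; the optional ``end_labels`` keep the written end
    annotations (e.g. ``("3'", "5'")``) as metadata only.  All composition
    and mass results are orientation-independent.
    """

    residues: tuple[str, ...]
    linkages: tuple[str, ...] = ()
    terminals: tuple[str, str] = (HYDROXYL, HYDROXYL)
    end_labels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("oligo must contain at least one residue")
        if len(self.linkages) != len(self.residues) - 1:
            raise ValueError(
                f"expected {len(self.residues) - 1} linkages, got {len(self.linkages)}"
            )
        for code in self.residues:
            if code not in RESIDUES:
                raise ValueError(f"unknown residue code {code!r}")
        for linkage in self.linkages:
            if linkage not in LINKAGE_DELTAS:
                raise ValueError(f"unknown linkage kind {linkage!r}")
        for terminal in self.terminals:
            if terminal not in TERMINAL_DELTAS:
                raise ValueError(f"unknown terminal group {terminal!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def serialize(self) -> str:
        """Hyphen-joined token string, reproducing end labels when present."""
        tokens = list(self.residues)
        if self.end_labels is not None:
            tokens = [self.end_labels[0], *tokens, self.end_labels[1]]
        return "-".join(tokens)

    def subsequence(
        self,
        start: int,
        stop: int,
        terminals: tuple[str, str] = (HYDROXYL, HYDROXYL),
    ) -> "ModifiedOligo":
        """Contiguous sub-oligo over the half-open span [start, stop)."""
        if not (0 <= start < stop <= len(self)):
            raise ValueError(f"invalid span [{start}, {stop}) for length {len(self)}")
        return ModifiedOligo(
            residues=self.residues[start:stop],
            linkages=self.linkages[start : stop - 1],
            terminals=terminals,
        )


class SequenceParseError(ValueError):
    """Raised when an oligonucleotide sequence string cannot be parsed."""


_END_LABEL = re.compile(r"^[35][''′]$")


def parse_sequence(text: str) -> ModifiedOligo:
    """Parse a hyphen-separated residue string, e.g. ``"3'-mU-mC-...-G-5'"``.

    End labels (3'/5'), when present, must appear at both ends and are kept
    verbatim as metadata.  All linkages default to phosphorothioate and both
    terminal groups default to hydroxyl.
    """
    tokens = [token.strip() for token in text.strip().split("-")]
    tokens = [token for token in tokens if token]
    if not tokens:
        raise SequenceParseError("empty sequence string")
    end_labels: tuple[str, str] | None = None
    first_is_label = bool(_END_LABEL.match(tokens[0]))
    last_is_label = bool(_END_LABEL.match(tokens[-1]))
    if first_is_label != last_is_label:
        raise SequenceParseError(
            "end labels must appear at both ends or not at all: "
            f"found {tokens[0]!r} ... {tokens[-1]!r}"
        )
    if first_is_label:
        if len(tokens) < 3:
            raise SequenceParseError("sequence contains end labels but no residues")
        end_labels = (tokens[0], tokens[-1])
        tokens = tokens[1:-1]
    for position, token in enumerate(tokens, start=1):
        if token not in RESIDUES:
            raise SequenceParseError(
                f"unknown residue token {token!r} at position {position}"
            )
    return ModifiedOligo(
        residues=tuple(tokens),
        linkages=(PHOSPHOROTHIOATE,) * (len(tokens) - 1),
        end_labels=end_labels,
    )


def formula_of(oligo: ModifiedOligo, abasic_positions: Iterable[int] = ()) -> Formula:
    """Elemental formula of an oligo: nucleosides + linkage and terminal deltas.

    ``abasic_positions`` marks residues whose nucleobase has been lost
    hydrolytically; those positions contribute the abasic MOE-ribose formula
    (nucleoside - base + H2O) instead of the intact nucleoside.
    """
    abasic = set(abasic_positions)
    bad = abasic - set(range(len(oligo)))
    if bad:
        raise ValueError(f"abasic positions {sorted(bad)} outside oligo of length {len(oligo)}")
    total = Formula()
    for index, code in enumerate(oligo.residues):
        residue = RESIDUES[code]
        total = total + (residue.abasic if index in abasic else residue.nucleoside)
    for linkage in oligo.linkages:
        total = total + LINKAGE_DELTAS[linkage]
    for terminal in oligo.terminals:
        total = total + TERMINAL_DELTAS[terminal]
    if not total.is_nonnegative():
        raise ValueError(f"computed formula has negative counts: {dict(total)}")
    return total


#: The nusinersen sequence as printed for the drug substance (18-mer, written
#: 3'->5' left to right; all linkages phosphorothioate; free-acid form).
NUSINERSEN_SEQUENCE = "3'-mU-mC-A-mC-mU-mU-mU-mC-A-mU-A-A-mU-G-mC-mU-G-G-5'"

NUSINERSEN: ModifiedOligo = parse_sequence(NUSINERSEN_SEQUENCE)
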