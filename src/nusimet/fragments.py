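"""Enumeration of the candidate metabolite space of an oligonucleotide.

Exonucleases chew antisense oligonucleotides from either end, so the plausible
metabolites of an n-mer are its contiguous sub-sequences ("shortmers"): 5'-end
products, 3'-end products, and both-end truncations.  On top of truncation,
serum metabolites show two further variations: the terminal chemistry left by
hydrolysis (free hydroxyl or a retained thiophosphate group at either end) and
hydrolytic loss of nucleobases (depurination/depyrimidination), which leaves an
abasic MOE-ribose ("MoeR") in place of the nucleoside.

This module generates that space exhaustively and deterministically.  Every
candidate keeps its span into the parent, so isobaric candidates (identical
formulas from different spans) are all retained and only *grouped* for
reporting, never silently merged.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    HYDROXYL,
    PHOSPHOROTHIOATE,
    RESIDUES,
    THIOPHOSPHATE,
    Formula,
    MassKind,
    ModifiedOligo,
    formula_of,
    mass,
)

__all__ = [
    "TruncationLabel",
    "FragmentCandidate",
    "ALL_TERMINAL_COMBINATIONS",
    "DEFAULT_TERMINAL_POLICY",
    "enumerate_truncations",
    "apply_terminal_policy",
    "enumerate_base_losses",
    "count_adjacent_runs",
    "canonical_label",
    "formula_groups",
    "default_candidate_space",
    "candidates_to_frame",
]

#: Terminal-group order used for deterministic sorting.
_TERMINAL_ORDER = {HYDROXYL: 0, THIOPHOSPHATE: 1}

ALL_TERMINAL_COMBINATIONS: tuple[tuple[str, str], ...] = (
    (HYDROXYL, HYDROXYL),
    (HYDROXYL, THIOPHOSPHATE),
    (THIOPHOSPHATE, HYDROXYL),
    (THIOPHOSPHATE, THIOPHOSPHATE),
)

#: Default policy: every terminal combination is considered plausible, since
#: hydrolysis may leave the bridging phosphorothioate on either product.
DEFAULT_TERMINAL_POLICY = ALL_TERMINAL_COMBINATIONS


@dataclass(frozen=True, order=True)
class TruncationLabel:
    """Residues removed from the left (written-3') and right (written-5') ends.

    The rendering convention is fixed by this package: the left end of the
    stored sequence carries the 3' label, matching the written orientation of
    the nusinersen constant.  Labels are always reported next to explicit
    spans, so no information depends on the convention.
    """

    a: int  # removed from the left (written-3') end
    b: int  # removed from the right (written-5') end

    def render(self) -> str:
        if self.a == 0 and self.b == 0:
            return "intact"
        if self.a == 0:
            return f"3'N-{self.b}"
        if self.b == 0:
            return f"5'N-{self.a}"
        return f"5'N-{self.a}+3'N-{self.b}"


@dataclass(frozen=True)
class FragmentCandidate:
    """A truncation/base-loss product of a parent oligonucleotide.

    ``span`` is a half-open 0-based interval into the parent (written order);
    ``losses`` holds parent positions whose nucleobase has been removed;
    ``terminals`` is the (left, right) terminal chemistry.  The formula and
    all three masses are precomputed at construction.
    """

    parent_length: int
    span: tuple[int, int]
    residues: tuple[str, ...]
    terminals: tuple[str, str]
    losses: frozenset[int]
    formula: Formula
    mass_monoisotopic: float
    mass_average: float
    mass_nominal: float

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def label(self) -> TruncationLabel:
        return TruncationLabel(a=self.span[0], b=self.parent_length - self.span[1])

    def mass(self, kind: MassKind | str = MassKind.MONOISOTOPIC) -> float:
        kind = MassKind(kind)
        if kind is MassKind.MONOISOTOPIC:
            return self.mass_monoisotopic
        if kind is MassKind.AVERAGE:
            return self.mass_average
        return self.mass_nominal

    @property
    def sequence(self) -> str:
        """Metabolite notation: ``*`` marks phosphorothioate bridges/terminals,
        ``MoeR`` an abasic ribose, e.g. ``"G*G*"`` or ``"*mU*mU*mU*MoeR"``."""
        tokens = [
            "MoeR" if position in self.losses else code
            for position, code in zip(range(self.span[0], self.span[1]), self.residues)
        ]
        body = "*".join(tokens)
        left = "*" if self.terminals[0] == THIOPHOSPHATE else ""
        right = "*" if self.terminals[1] == THIOPHOSPHATE else ""
        return left + body + right

    def sort_key(self) -> tuple:
        return (
            self.span,
            _TERMINAL_ORDER[self.terminals[0]],
            _TERMINAL_ORDER[self.terminals[1]],
            tuple(sorted(self.losses)),
        )


def _build_candidate(
    parent: ModifiedOligo,
    span: tuple[int, int],
    terminals: tuple[str, str],
    losses: frozenset[int],
) -> FragmentCandidate:
    sub = parent.subsequence(span[0], span[1], terminals=terminals)
    local_losses = [position - span[0] for position in losses]
    formula = formula_of(sub, abasic_positions=local_losses)
    return FragmentCandidate(
        parent_length=len(parent),
        span=span,
        residues=sub.residues,
        terminals=terminals,
        losses=losses,
        formula=formula,
        mass_monoisotopic=mass(formula, MassKind.MONOISOTOPIC),
        mass_average=mass(formula, MassKind.AVERAGE),
        mass_nominal=mass(formula, MassKind.NOMINAL),
    )


def enumerate_truncations(
    oligo: ModifiedOligo,
    min_len: int,
    max_len: int,
    include_full: bool = False,
) -> list[FragmentCandidate]:
    """All contiguous spans with min_len <= length <= max_len.

    Candidates carry hydroxyl termini and no base losses; the full-length span
    is included only when ``include_full`` is set.
    """
    n = len(oligo)
    if not (1 <= min_len <= max_len <= n):
        raise ValueError(
            f"invalid length bounds [{min_len}, {max_len}] for parent of length {n}"
        )
    candidates = []
    for length in range(min_len, max_len + 1):
        for start in range(0, n - length + 1):
            span = (start, start + length)
            if span == (0, n) and not include_full:
                continue
            candidates.append(
                _build_candidate(oligo, span, (HYDROXYL, HYDROXYL), frozenset())
            )
    return candidates


def apply_terminal_policy(
    candidates: Sequence[FragmentCandidate],
    policy: Sequence[tuple[str, str]],
    parent: ModifiedOligo,
) -> list[FragmentCandidate]:
    """Expand each candidate to one variant per allowed terminal combination."""
    combos = list(dict.fromkeys(tuple(combo) for combo in policy))
    if not combos:
        raise ValueError("terminal policy must allow at least one combination")
    for combo in combos:
        for terminal in combo:
            if terminal not in (HYDROXYL, THIOPHOSPHATE):
                raise ValueError(f"unknown terminal group {terminal!r}")
    expanded: list[FragmentCandidate] = []
    seen: set[tuple] = set()
    for candidate in candidates:
        for combo in combos:
            key = (candidate.span, combo, candidate.losses)
            if key in seen:
                raise ValueError(f"duplicate candidate {key}")
            seen.add(key)
            expanded.append(_build_candidate(parent, candidate.span, combo, candidate.losses))
    return expanded


def enumerate_base_losses(
    candidates: Sequence[FragmentCandidate],
    max_losses: int,
    parent: ModifiedOligo,
) -> list[FragmentCandidate]:
    """Expand candidates with every base-loss subset of size <= max_losses.

    Base loss retains the sugar as abasic MOE-ribose (formula - base + H2O).
    Candidates that end up with identical formulas (e.g. loss of either G of a
    G*G* dimer) are all retained; use :func:`formula_groups` to group isobars.
    """
    if max_losses < 0:
        raise ValueError("max_losses must be >= 0")
    expanded: list[FragmentCandidate] = []
    for candidate in candidates:
        positions = range(candidate.span[0], candidate.span[1])
        expanded.append(candidate)
        for k in range(1, max_losses + 1):
            for subset in itertools.combinations(positions, k):
                losses = candidate.losses | frozenset(subset)
                if len(losses) != len(candidate.losses) + k:
                    continue
                expanded.append(
                    _build_candidate(parent, candidate.span, candidate.terminals, losses)
                )
    return expanded


def count_adjacent_runs(oligo: ModifiedOligo, composition: Iterable[str]) -> int:
    """Number of contiguous windows whose residue multiset equals ``composition``.

    The comparison is orientation-free (a multiset ignores reading direction),
    so e.g. the {mU, mC} dinucleotide occurs 4 times in nusinersen.
    """
    wanted = Counter(composition)
    k = sum(wanted.values())
    if k < 2:
        raise ValueError("composition must contain at least 2 residues")
    for code in wanted:
        if code not in RESIDUES:
            raise ValueError(f"unknown residue code {code!r}")
    n = len(oligo)
    if k > n:
        return 0
    window = Counter(oligo.residues[:k])
    count = 1 if window == wanted else 0
    for i in range(k, n):
        window[oligo.residues[i]] += 1
        window[oligo.residues[i - k]] -= 1
        if window[oligo.residues[i - k]] == 0:
            del window[oligo.residues[i - k]]
        if window == wanted:
            count += 1
    return count


def canonical_label(candidate: FragmentCandidate) -> str:
    """Rendered truncation label under this package's fixed convention."""
    return candidate.label.render()


def formula_groups(
    candidates: Sequence[FragmentCandidate],
) -> dict[Formula, list[FragmentCandidate]]:
    """Partition candidates by elemental formula (isobar grouping view)."""
    groups: dict[Formula, list[FragmentCandidate]] = {}
    for candidate in sorted(candidates, key=FragmentCandidate.sort_key):
        groups.setdefault(candidate.formula, []).append(candidate)
    return groups


def default_candidate_space(
    parent: ModifiedOligo,
    min_len: int = 2,
    max_len: int = 4,
    terminal_policy: Sequence[tuple[str, str]] = DEFAULT_TERMINAL_POLICY,
    max_base_losses: int = 1,
) -> list[FragmentCandidate]:
    """The candidate space used for identification runs.

    Defaults cover 2-4-mer shortmers (the observed metabolite length range),
    all four terminal-group combinations and at most one base loss.
    """
    truncations = enumerate_truncations(parent, min_len, max_len, include_full=False)
    with_terminals = apply_terminal_policy(truncations, terminal_policy, parent)
    with_losses = enumerate_base_losses(with_terminals, max_base_losses, parent)
    return sorted(with_losses, key=FragmentCandidate.sort_key)


def candidates_to_frame(candidates: Sequence[FragmentCandidate]) -> pd.DataFrame:
    """Tabular export: span, label, sequence, formula (Hill), masses, variants."""
    rows = []
    for candidate in candidates:
        rows.append(
            {
                "span_start": candidate.span[0],
                "span_stop": candidate.span[1],
                "label": candidate.label.render(),
                "sequence": candidate.sequence,
                "formula": candidate.formula.hill(),
                "mass_monoisotopic": candidate.mass_monoisotopic,
                "mass_average": candidate.mass_average,
                "mass_nominal": candidate.mass_nominal,
                "terminal_left": candidate.terminals[0],
                "terminal_right": candidate.terminals[1],
                "base_losses": ";".join(str(p) for p in sorted(candidate.losses)),
            }
        )
    return pd.DataFrame(rows)


_SEQ_TOKEN = re.compile(r"mU|mC|A|G|MoeR|\*")


def parse_candidate_sequence(text: str) -> tuple[tuple[str, ...], tuple[str, str]]:
    """Parse a metabolite notation string back into tokens and terminals.

    Returns the residue/abasic token tuple and the (left, right) terminal
    groups; used to check that candidate sequence strings round-trip.
    """
    tokens = _SEQ_TOKEN.findall(text)
    if "".join(tokens) != text.replace(" ", ""):
        raise ValueError(f"cannot parse candidate sequence {text!r}")
    left = THIOPHOSPHATE if tokens and tokens[0] == "*" else HYDROXYL
    right = THIOPHOSPHATE if len(tokens) > 1 and tokens[-1] == "*" else HYDROXYL
    residues = tuple(token for token in tokens if token != "*")
    if not residues:
        raise ValueError(f"no residues in candidate sequence {text!r}")
    return residues, (left, right)
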