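"""Pipeline driver: match deconvolved species to candidate metabolites.

The identification pipeline composes three stages: (1) ion pairing and
neutral-mass deconvolution (:mod:`nusimet.spectra`), (2) candidate matching
against the enumerated truncation/base-loss space (:mod:`nusimet.fragments`),
and (3) co-elution confirmation.  Isobaric ambiguity is a first-class outcome:
when several distinct elemental compositions fall within the match tolerance
the species is reported as ambiguous with the full "or"-list of candidates,
never resolved by retention modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chem import MassKind, ModifiedOligo, NUSINERSEN
from .config import RunConfig
from .fragments import FragmentCandidate, default_candidate_space
from .spectra import DeconvolvedSpecies, ObservedIon, pair_ions

__all__ = [
    "Assignment",
    "AssignmentTable",
    "match_candidates",
    "coelution_confirm",
    "run_identification",
    "summarize",
]

STATUS_IDENTIFIED = "identified"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNIDENTIFIED = "unidentified"
STATUS_UNCONFIRMED = "unconfirmed"


@dataclass(frozen=True)
class Assignment:
    """A deconvolved species with its ranked candidate list and status.

    ``candidates`` holds (candidate, mass delta) pairs sorted by |delta| then
    span; ``status`` is one of identified / ambiguous (>= 2 isobaric formula
    groups) / unidentified (no candidate in tolerance) / unconfirmed
    (single-ion species, candidates still listed).
    """

    species: DeconvolvedSpecies
    candidates: tuple[tuple[FragmentCandidate, float], ...]
    status: str
    coeluting: bool

    @property
    def n_formula_groups(self) -> int:
        return len({candidate.formula for candidate, _ in self.candidates})

    @property
    def best(self) -> FragmentCandidate | None:
        return self.candidates[0][0] if self.candidates else None


@dataclass(frozen=True)
class AssignmentTable:
    """Ordered assignments plus the configuration snapshot that produced them."""

    assignments: tuple[Assignment, ...]
    config: RunConfig

    def __len__(self) -> int:
        return len(self.assignments)

    def __iter__(self):
        return iter(self.assignments)


def _status_of(species: DeconvolvedSpecies, n_groups: int) -> str:
    if n_groups == 0:
        return STATUS_UNIDENTIFIED
    if not species.confirmed:
        return STATUS_UNCONFIRMED
    return STATUS_AMBIGUOUS if n_groups >= 2 else STATUS_IDENTIFIED


def match_candidates(
    species: DeconvolvedSpecies,
    candidates: Sequence[FragmentCandidate],
    tol: float = 2.5,
    mass_kind: MassKind | str = MassKind.MONOISOTOPIC,
) -> Assignment:
    """Candidates whose mass lies within ``tol`` Da of the species mass.

    Sorted by |mass delta|, then span start, then the deterministic candidate
    key, so identical inputs always give byte-identical output tables.
    """
    if tol <= 0:
        raise ValueError("match tolerance must be positive")
    kind = MassKind(mass_kind)
    hits: list[tuple[FragmentCandidate, float]] = []
    for candidate in candidates:
        delta = candidate.mass(kind) - species.mass
        if abs(delta) <= tol:
            hits.append((candidate, delta))
    hits.sort(key=lambda pair: (abs(pair[1]), pair[0].sort_key()))
    n_groups = len({candidate.formula for candidate, _ in hits})
    return Assignment(
        species=species,
        candidates=tuple(hits),
        status=_status_of(species, n_groups),
        coeluting=species.confirmed,
    )


def coelution_confirm(assignment: Assignment, rt_tol: float = 0.1) -> Assignment:
    """Re-evaluate the co-elution flag: confirmed iff >= 2 supporting ions
    with all pairwise rt differences within ``rt_tol``."""
    ions = assignment.species.ions
    confirmed = len(ions) >= 2 and all(
        abs(a.rt - b.rt) <= rt_tol for i, a in enumerate(ions) for b in ions[i + 1 :]
    )
    status = assignment.status
    if not confirmed and status in (STATUS_IDENTIFIED, STATUS_AMBIGUOUS):
        status = STATUS_UNCONFIRMED
    elif confirmed and status == STATUS_UNCONFIRMED and assignment.candidates:
        status = (
            STATUS_AMBIGUOUS if assignment.n_formula_groups >= 2 else STATUS_IDENTIFIED
        )
    return Assignment(
        species=assignment.species,
        candidates=assignment.candidates,
        status=status,
        coeluting=confirmed,
    )


def run_identification(
    ions: Sequence[ObservedIon],
    config: RunConfig | None = None,
    parent: ModifiedOligo = NUSINERSEN,
    candidates: Sequence[FragmentCandidate] | None = None,
) -> AssignmentTable:
    """Deconvolute a peak list and assign candidates, ordered by consensus rt.

    The candidate space defaults to the configured truncation/terminal/base-loss
    enumeration of ``parent``; pass ``candidates`` to reuse a prebuilt space.
    """
    config = config or RunConfig()
    if candidates is None:
        candidates = default_candidate_space(
            parent,
            min_len=config.min_len,
            max_len=config.max_len,
            terminal_policy=config.terminal_policy,
            max_base_losses=config.max_base_losses,
        )
    species_list = pair_ions(
        ions, mass_tol=config.pair_mass_tol, rt_tol=config.pair_rt_tol
    )
    assignments = []
    for species in species_list:
        assignment = match_candidates(
            species, candidates, tol=config.match_tol, mass_kind=config.mass_kind
        )
        assignments.append(coelution_confirm(assignment, rt_tol=config.pair_rt_tol))
    assignments.sort(key=lambda a: (a.species.rt, a.species.mass))
    return AssignmentTable(assignments=tuple(assignments), config=config)


def _candidate_class(candidate: FragmentCandidate) -> str:
    if candidate.losses:
        return "base_loss"
    label = candidate.label
    if label.a == 0 and label.b == 0:
        return "intact"
    if label.a > 0 and label.b > 0:
        return "both_end"
    return "single_end"


def summarize(table: AssignmentTable) -> dict:
    """Summary record: status counts, metabolite mass range, class counts.

    The mass range is reported over species that received at least one
    candidate, in two variants: the deconvoluted consensus masses and the
    best-candidate masses.
    """
    status_counts = {
        status: 0
        for status in (
            STATUS_IDENTIFIED,
            STATUS_AMBIGUOUS,
            STATUS_UNCONFIRMED,
            STATUS_UNIDENTIFIED,
        )
    }
    consensus_masses: list[float] = []
    candidate_masses: list[float] = []
    length_counts: dict[int, int] = {}
    class_counts: dict[str, int] = {}
    for assignment in table:
        status_counts[assignment.status] += 1
        best = assignment.best
        if best is not None:
            consensus_masses.append(assignment.species.mass)
            candidate_masses.append(best.mass(table.config.mass_kind))
            length_counts[best.length] = length_counts.get(best.length, 0) + 1
            cls = _candidate_class(best)
            class_counts[cls] = class_counts.get(cls, 0) + 1
    def _range(values: list[float]) -> tuple[float, float] | None:
        return (min(values), max(values)) if values else None

    return {
        "n_species": len(table),
        "status_counts": status_counts,
        "mass_range_consensus": _range(consensus_masses),
        "mass_range_best_candidate": _range(candidate_masses),
        "length_counts": dict(sorted(length_counts.items())),
        "class_counts": dict(sorted(class_counts.items())),
    }
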