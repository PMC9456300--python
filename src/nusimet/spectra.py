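"""Spectral primitives for negative-mode ESI oligonucleotide data.

Oligonucleotide metabolites ionise in negative mode by losing protons from the
phosphate backbone, so one metabolite shows up as a small set of ions at
charges -1 and -2.  Identification proceeds in three steps: the charge state is
read off the isotope-peak spacing (1/|z|), each ion is deconvoluted to a
neutral mass M = |z|*(m/z) + |z|*m_H+, and ions whose neutral masses and
retention times agree are grouped into one deconvolved species whose consensus
mass is the mean of the per-ion estimates.  Co-elution of a -1/-2 pair is the
confirmation signal that both ions come from a single compound.

Isotope envelopes are predicted by exact elemental convolution: the per-element
isotopologue distribution (multinomial in the atom count) is convolved across
elements and aggregated on a nominal-mass grid, matching the unit resolution of
Q-TOF envelopes of 600-1700 m/z oligonucleotide ions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import PROTON_MASS, Formula, IsotopeTable

__all__ = [
    "ObservedIon",
    "IsotopeEnvelope",
    "DeconvolvedSpecies",
    "isotope_pattern",
    "charge_from_spacing",
    "neutral_mass",
    "mz_from_mass",
    "pair_ions",
]

_ALLOWED_CHARGES = (1, 2, 3, 4)


@dataclass(frozen=True, order=True)
class ObservedIon:
    """A centroided ion: m/z, charge magnitude (negative mode), rt, intensity."""

    mz: float
    z: int
    rt: float
    intensity: float = 0.0
    charge_known: bool = True

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.z not in _ALLOWED_CHARGES:
            raise ValueError(f"charge magnitude must be in {_ALLOWED_CHARGES}, got {self.z}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Predicted isotopologue peaks of one species at one charge state."""

    peaks: tuple[tuple[float, float], ...]  # (m/z, relative abundance)
    z: int

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if sorted(mzs) != mzs:
            raise ValueError("envelope m/z values must be strictly increasing")
        total = sum(a for _, a in self.peaks)
        if self.peaks and abs(total - 1.0) > 1e-6:
            raise ValueError(f"envelope abundances sum to {total}, expected 1")

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.peaks)


def _element_distribution(
    isotopes: Sequence[tuple[float, float]], count: int
) -> dict[int, tuple[float, float]]:
    """Isotopologue distribution of ``count`` atoms of one element.

    Returns nominal-mass offset -> (probability, probability-weighted mass),
    computed by binary-exponentiation convolution of the single-atom
    distribution.
    """
    mono_nominal = round(max(isotopes, key=lambda iso: iso[1])[0])
    single: dict[int, tuple[float, float]] = {}
    for m, a in isotopes:
        offset = round(m) - mono_nominal
        p, wm = single.get(offset, (0.0, 0.0))
        single[offset] = (p + a, wm + a * m)
    result: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    base = single
    remaining = count
    while remaining:
        if remaining & 1:
            result = _convolve(result, base)
        remaining >>= 1
        if remaining:
            base = _convolve(base, base)
    return result


def _convolve(
    a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]
) -> dict[int, tuple[float, float]]:
    # Mean-mass bookkeeping: for independent parts X and Y,
    # E[mass | X+Y at bin k] accumulates p_a * wm_b + p_b * wm_a contributions.
    out: dict[int, tuple[float, float]] = {}
    for ka, (pa, wa) in a.items():
        for kb, (pb, wb) in b.items():
            k = ka + kb
            p, w = out.get(k, (0.0, 0.0))
            out[k] = (p + pa * pb, w + pa * wb + pb * wa)
    return out


def isotope_pattern(
    formula: Formula,
    z: int,
    prune: float = 1e-4,
    table: IsotopeTable | None = None,
) -> IsotopeEnvelope:
    """Predict the isotope envelope of ``formula`` observed at charge ``-z``.

    Exact per-element multinomial expansion convolved across elements,
    aggregated on a nominal-mass grid; isotopologue masses are centroids per
    bin.  Peaks below the ``prune`` abundance fraction are removed and the
    remainder renormalized.  m/z = (M_isotopologue - z * m_H+) / z.
    """
    if z == 0:
        raise ValueError("charge must be nonzero")
    if not (0 <= prune < 1):
        raise ValueError("prune threshold must be in [0, 1)")
    table = table or IsotopeTable.default()
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for element, count in formula.items():
        dist = _convolve(dist, _element_distribution(table.isotopes(element), count))
    peaks = []
    for offset in sorted(dist):
        p, wm = dist[offset]
        if p <= 0:
            continue
        mass_centroid = wm / p
        peaks.append((mass_centroid, p))
    kept = [(m, p) for m, p in peaks if p >= prune]
    if not kept:  # degenerate prune: keep the base peak
        kept = [max(peaks, key=lambda mp: mp[1])]
    total = sum(p for _, p in kept)
    z_mag = abs(z)
    # inline m/z conversion: the degenerate empty formula yields a nonpositive
    # "m/z" placeholder rather than an error
    envelope = tuple(
        ((m - z_mag * PROTON_MASS) / z_mag, p / total) for m, p in kept
    )
    return IsotopeEnvelope(peaks=envelope, z=z_mag)


def charge_from_spacing(
    envelope: IsotopeEnvelope | Iterable[float],
    tolerance: float = 0.02,
) -> int | None:
    """Charge magnitude from isotope-peak spacing, or None if indeterminate.

    z = round(1 / median successive spacing), accepted only if every spacing
    is within ``tolerance`` of 1/z and z is in 1..4.
    """
    mzs = list(envelope.mzs) if isinstance(envelope, IsotopeEnvelope) else sorted(envelope)
    if len(mzs) < 2:
        raise ValueError("need at least two peaks to determine a charge state")
    spacings = [b - a for a, b in zip(mzs, mzs[1:])]
    spacings_sorted = sorted(spacings)
    mid = len(spacings_sorted) // 2
    if len(spacings_sorted) % 2:
        median = spacings_sorted[mid]
    else:
        median = 0.5 * (spacings_sorted[mid - 1] + spacings_sorted[mid])
    if median <= 0:
        return None
    z = round(1.0 / median)
    if z not in _ALLOWED_CHARGES:
        return None
    if any(abs(s - 1.0 / z) > tolerance for s in spacings):
        return None
    return z


def neutral_mass(ion: ObservedIon) -> float:
    """Neutral mass of a negative ion: M = |z|*(m/z) + |z|*m_H+ (proton restoration)."""
    return ion.z * ion.mz + ion.z * PROTON_MASS


def mz_from_mass(M: float, z: int) -> float:
    """m/z of the [M - zH]^z- ion: (M - z*m_H+)/z. Inverse of :func:`neutral_mass`."""
    if z <= 0:
        raise ValueError("charge magnitude must be positive")
    mz = (M - z * PROTON_MASS) / z
    if mz <= 0:
        raise ValueError(f"nonpositive m/z for M={M}, z={z}")
    return mz


@dataclass(frozen=True)
class DeconvolvedSpecies:
    """A neutral-mass species supported by one or more co-eluting ions.

    The consensus mass is the unweighted mean of the per-ion estimates; the
    consensus retention time is the intensity-weighted mean of the ion rts.
    A species supported by a single ion is flagged unconfirmed.
    """

    mass: float
    rt: float
    ions: tuple[ObservedIon, ...]
    estimates: tuple[float, ...]

    @property
    def confirmed(self) -> bool:
        return len(self.ions) >= 2

    @property
    def charge_states(self) -> tuple[int, ...]:
        return tuple(sorted({ion.z for ion in self.ions}))


def _make_species(ions: Sequence[ObservedIon]) -> DeconvolvedSpecies:
    estimates = tuple(neutral_mass(ion) for ion in ions)
    total_intensity = sum(ion.intensity for ion in ions)
    if total_intensity > 0:
        rt = sum(ion.rt * ion.intensity for ion in ions) / total_intensity
    else:
        rt = sum(ion.rt for ion in ions) / len(ions)
    return DeconvolvedSpecies(
        mass=sum(estimates) / len(estimates),
        rt=rt,
        ions=tuple(ions),
        estimates=estimates,
    )


def pair_ions(
    ions: Sequence[ObservedIon],
    mass_tol: float = 0.2,
    rt_tol: float = 0.1,
) -> list[DeconvolvedSpecies]:
    """Group ions into deconvolved species by neutral mass and co-elution.

    Greedy complete-linkage grouping in descending intensity order (ties
    broken by lower m/z): an ion joins a species only if its neutral-mass
    estimate is within ``mass_tol`` and its rt within ``rt_tol`` of *every*
    ion already in the species.  Unpaired ions become single-ion species
    (flagged unconfirmed).  Output is ordered by consensus rt, then mass.
    """
    if mass_tol <= 0 or rt_tol <= 0:
        raise ValueError("mass_tol and rt_tol must be positive")
    order = sorted(ions, key=lambda ion: (-ion.intensity, ion.mz, ion.rt))
    used = [False] * len(order)
    species: list[DeconvolvedSpecies] = []
    masses = [neutral_mass(ion) for ion in order]
    for i, seed in enumerate(order):
        if used[i]:
            continue
        used[i] = True
        members = [i]
        for j in range(len(order)):
            if used[j]:
                continue
            ok = all(
                abs(masses[j] - masses[k]) <= mass_tol
                and abs(order[j].rt - order[k].rt) <= rt_tol
                for k in members
            )
            if ok:
                used[j] = True
                members.append(j)
        species.append(_make_species([order[k] for k in members]))
    species.sort(key=lambda s: (s.rt, s.mass))
    return species
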