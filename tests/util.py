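"""Shared helpers for the test suite."""

from __future__ import annotations

import itertools


def fragment_key(candidate):
    return (candidate.span, candidate.terminals, candidate.losses)


def recall_of(truth, table) -> float:
    """Fraction of planted metabolites whose true fragment appears in some
    assignment's candidate list."""
    keys = {
        key
        for assignment in table
        for key in (fragment_key(c) for c, _ in assignment.candidates)
    }
    hits = sum(fragment_key(met.fragment) in keys for met in truth)
    return hits / len(truth)


def count_cross_metabolite_mergers(sample, table) -> int:
    """Number of deconvolved species containing ions from >1 truth metabolite."""
    origin = dict(zip(sample.ions, sample.manifest["origin"]))
    mergers = 0
    for assignment in table:
        metabolites = {
            origin[ion]
            for ion in assignment.species.ions
            if origin.get(ion, "").startswith("metabolite")
        }
        if len(metabolites) > 1:
            mergers += 1
    return mergers


def brute_force_envelope(formula, isotope_table):
    """Exhaustive isotopologue enumeration (feasible for <= ~12 atoms).

    Returns {nominal-offset: (probability, centroid mass)} aggregated on the
    same nominal grid as the convolution implementation.
    """
    atoms = []
    for element, count in formula.items():
        isotopes = isotope_table.isotopes(element)
        mono_nominal = round(max(isotopes, key=lambda iso: iso[1])[0])
        atoms.extend([[(round(m) - mono_nominal, m, a) for m, a in isotopes]] * count)
    bins: dict[int, tuple[float, float]] = {}
    for combo in itertools.product(*atoms) if atoms else [()]:
        offset = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        prob = 1.0
        for c in combo:
            prob *= c[2]
        p, wm = bins.get(offset, (0.0, 0.0))
        bins[offset] = (p + prob, wm + prob * mass)
    return {k: (p, wm / p) for k, (p, wm) in bins.items() if p > 0}
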