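"""Isotope patterns, charge determination, deconvolution and ion pairing."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from nusimet.chem import Formula, IsotopeTable, PROTON_MASS
from nusimet.spectra import (
    ObservedIon,
    charge_from_spacing,
    isotope_pattern,
    mz_from_mass,
    neutral_mass,
    pair_ions,
)
from util import brute_force_envelope


class TestIsotopePattern:
    def test_empty_formula_single_peak(self):
        envelope = isotope_pattern(Formula(), z=1)
        assert len(envelope.peaks) == 1
        assert envelope.abundances[0] == pytest.approx(1.0)

    def test_two_carbons_plus_one_ratio(self):
        envelope = isotope_pattern(Formula.parse("C2"), z=1, prune=0.0)
        ratio = envelope.abundances[1] / envelope.abundances[0]
        assert ratio == pytest.approx(2 * 0.0107 / 0.9893, rel=1e-6)

    def test_sulfur_plus_two_ratio(self):
        envelope = isotope_pattern(Formula.parse("S"), z=1, prune=0.0)
        # peaks: 32S, 33S, 34S, 36S -> +2 peak is index 2
        ratio = envelope.abundances[2] / envelope.abundances[0]
        assert ratio == pytest.approx(0.0425 / 0.9499, rel=1e-6)

    def test_charge_scaling_of_spacing(self):
        f = Formula.parse("C26H38N10O15P2S2")
        for z in (1, 2):
            envelope = isotope_pattern(f, z=z, prune=1e-3)
            spacings = [b - a for a, b in zip(envelope.mzs, envelope.mzs[1:])]
            assert all(abs(s - 1.0 / z) < 0.02 for s in spacings)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(Formula.parse("C2"), z=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["H", "C", "N", "O", "P", "S"]),
            st.integers(min_value=0, max_value=4),
        ).map(Formula).filter(lambda f: 0 < f.total_atoms() <= 12)
    )
    def test_convolution_equals_brute_force_enumeration(self, formula):
        table = IsotopeTable.default()
        oracle = brute_force_envelope(formula, table)
        envelope = isotope_pattern(formula, z=1, prune=0.0)
        assert len(envelope.peaks) == len(oracle)
        for (mz, abundance), offset in zip(envelope.peaks, sorted(oracle)):
            p, centroid = oracle[offset]
            assert abundance == pytest.approx(p, abs=1e-9)
            assert mz == pytest.approx(centroid - PROTON_MASS, abs=1e-7)


class TestChargeFromSpacing:
    def test_unit_spacing_is_singly_charged(self):
        assert charge_from_spacing([500.0, 501.003, 502.006]) == 1

    def test_half_spacing_is_doubly_charged(self):
        assert charge_from_spacing([500.0, 500.5006, 501.0012]) == 2

    def test_out_of_range_spacing_indeterminate(self):
        assert charge_from_spacing([500.0, 500.21, 500.42]) is None

    def test_inconsistent_spacings_indeterminate(self):
        assert charge_from_spacing([500.0, 501.0, 501.5]) is None

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            charge_from_spacing([500.0])

    def test_recovers_charge_of_predicted_envelopes(self, candidate_space):
        rng = random.Random(3)
        for candidate in rng.sample(candidate_space, 10):
            for z in (1, 2, 3):
                envelope = isotope_pattern(candidate.formula, z=z, prune=1e-3)
                if len(envelope.peaks) >= 2:
                    assert charge_from_spacing(envelope) == z


class TestNeutralMass:
    @pytest.mark.parametrize(
        "mz,z,expected",
        [(855.30, 1, 856.31), (731.31, 2, 1464.63), (617.73, 2, 1237.47)],
    )
    def test_reported_ion_examples(self, mz, z, expected):
        ion = ObservedIon(mz=mz, z=z, rt=9.0, intensity=1.0)
        assert neutral_mass(ion) == pytest.approx(expected, abs=0.02)

    def test_mz_from_mass_examples(self):
        assert mz_from_mass(1237.47, 1) == pytest.approx(1236.46, abs=0.02)
        assert mz_from_mass(101.007276, 1) == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            mz_from_mass(2.014552, 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=100.0, max_value=5000.0),
        st.integers(min_value=1, max_value=4),
    )
    def test_exact_inverses(self, M, z):
        mz = mz_from_mass(M, z)
        ion = ObservedIon(mz=mz, z=z, rt=1.0, intensity=1.0)
        assert neutral_mass(ion) == pytest.approx(M, abs=1e-9)
        assert mz_from_mass(neutral_mass(ion), z) == pytest.approx(mz, abs=1e-9)


class TestPairIons:
    def test_reported_pair_joins_into_one_species(self):
        ions = [
            ObservedIon(mz=617.73, z=2, rt=10.45, intensity=2.0),
            ObservedIon(mz=1236.46, z=1, rt=10.45, intensity=1.0),
        ]
        (species,) = pair_ions(ions, mass_tol=0.2, rt_tol=0.1)
        assert species.confirmed
        assert species.mass == pytest.approx(1237.47, abs=0.02)
        assert species.charge_states == (1, 2)

    def test_mass_and_rt_gap_keeps_species_apart(self):
        # neutral masses ~0.97 Da apart AND rts 0.23 min apart
        ions = [
            ObservedIon(mz=696.76, z=2, rt=10.60, intensity=1.0),
            ObservedIon(mz=1395.51, z=1, rt=10.83, intensity=1.0),
        ]
        species = pair_ions(ions, mass_tol=0.2, rt_tol=0.1)
        assert len(species) == 2
        assert all(not s.confirmed for s in species)

    def test_single_ion_is_unconfirmed_species(self):
        (species,) = pair_ions([ObservedIon(mz=855.30, z=1, rt=8.81, intensity=1.0)])
        assert not species.confirmed and len(species.ions) == 1

    def test_consensus_rt_is_intensity_weighted(self):
        ions = [
            ObservedIon(mz=1000.0, z=1, rt=9.00, intensity=3.0),
            ObservedIon(mz=499.5, z=2, rt=9.04, intensity=1.0),
        ]
        (species,) = pair_ions(ions, mass_tol=0.2, rt_tol=0.1)
        assert species.rt == pytest.approx(9.01)

    def test_never_merges_beyond_mass_tol(self):
        rng = random.Random(5)
        ions = [
            ObservedIon(
                mz=rng.uniform(500, 1500),
                z=rng.choice([1, 2]),
                rt=rng.uniform(8.5, 11.0),
                intensity=rng.uniform(1, 100),
            )
            for _ in range(60)
        ]
        for species in pair_ions(ions, mass_tol=0.2, rt_tol=0.1):
            for e1, e2 in itertools.combinations(species.estimates, 2):
                assert abs(e1 - e2) <= 0.2

    def test_permutation_invariance(self):
        rng = random.Random(9)
        ions = [
            ObservedIon(
                mz=rng.uniform(500, 1500),
                z=rng.choice([1, 2]),
                rt=rng.uniform(8.5, 11.0),
                intensity=rng.uniform(1, 100),
            )
            for _ in range(40)
        ]
        reference = pair_ions(ions)
        for _ in range(3):
            rng.shuffle(ions)
            assert pair_ions(ions) == reference

    def test_invalid_tolerances_rejected(self):
        with pytest.raises(ValueError):
            pair_ions([], mass_tol=0.0)


def test_observed_ion_validation():
    with pytest.raises(ValueError):
        ObservedIon(mz=-5.0, z=1, rt=1.0)
    with pytest.raises(ValueError):
        ObservedIon(mz=500.0, z=5, rt=1.0)
    with pytest.raises(ValueError):
        ObservedIon(mz=500.0, z=1, rt=1.0, intensity=-1.0)
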