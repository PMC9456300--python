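"""Truncation / base-loss candidate enumeration."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from nusimet.chem import (
    HYDROXYL,
    NUSINERSEN,
    PHOSPHOROTHIOATE,
    RESIDUES,
    THIOPHOSPHATE,
    Formula,
    ModifiedOligo,
    mass,
)
from nusimet.fragments import (
    ALL_TERMINAL_COMBINATIONS,
    apply_terminal_policy,
    canonical_label,
    count_adjacent_runs,
    default_candidate_space,
    enumerate_base_losses,
    enumerate_truncations,
    formula_groups,
    candidates_to_frame,
    parse_candidate_sequence,
)


def random_oligo(codes):
    return ModifiedOligo(tuple(codes), (PHOSPHOROTHIOATE,) * (len(codes) - 1))


class TestEnumerateTruncations:
    def test_proper_span_count_of_18mer(self):
        assert len(enumerate_truncations(NUSINERSEN, 1, 17)) == 170

    def test_2_to_4_mer_count(self):
        assert len(enumerate_truncations(NUSINERSEN, 2, 4)) == 48

    def test_full_length_span(self):
        (candidate,) = enumerate_truncations(NUSINERSEN, 18, 18, include_full=True)
        assert candidate.span == (0, 18)
        assert candidate.label.a == 0 and candidate.label.b == 0
        assert canonical_label(candidate) == "intact"

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            enumerate_truncations(NUSINERSEN, 0, 4)
        with pytest.raises(ValueError):
            enumerate_truncations(NUSINERSEN, 5, 19)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from(sorted(RESIDUES)), min_size=1, max_size=8),
        st.data(),
    )
    def test_count_matches_closed_form_and_spans_unique(self, codes, data):
        parent = random_oligo(codes)
        n = len(parent)
        min_len = data.draw(st.integers(1, n))
        max_len = data.draw(st.integers(min_len, n))
        candidates = enumerate_truncations(parent, min_len, max_len, include_full=True)
        expected = sum(n - length + 1 for length in range(min_len, max_len + 1))
        assert len(candidates) == expected
        assert len({c.span for c in candidates}) == expected


class TestTerminalPolicy:
    def test_cartesian_expansion(self):
        base = enumerate_truncations(NUSINERSEN, 2, 2)[:1]
        expanded = apply_terminal_policy(base, ALL_TERMINAL_COMBINATIONS, NUSINERSEN)
        assert len(expanded) == 4
        assert len({c.terminals for c in expanded}) == 4

    def test_empty_policy_rejected(self):
        base = enumerate_truncations(NUSINERSEN, 2, 2)[:1]
        with pytest.raises(ValueError, match="policy"):
            apply_terminal_policy(base, [], NUSINERSEN)

    def test_gg_span_masses(self):
        gg = [c for c in enumerate_truncations(NUSINERSEN, 2, 2) if c.residues == ("G", "G")]
        assert len(gg) == 1
        variants = {
            c.terminals: c
            for c in apply_terminal_policy(gg, ALL_TERMINAL_COMBINATIONS, NUSINERSEN)
        }
        assert variants[(HYDROXYL, HYDROXYL)].mass_monoisotopic == pytest.approx(
            760.199, abs=5e-3
        )
        assert variants[(HYDROXYL, THIOPHOSPHATE)].mass_monoisotopic == pytest.approx(
            856.143, abs=5e-3
        )
        assert variants[(HYDROXYL, THIOPHOSPHATE)].sequence == "G*G*"


class TestBaseLosses:
    def test_single_loss_expansion_and_formula(self):
        # span A,mC,mU contains exactly one adenine
        span = [
            c
            for c in enumerate_truncations(NUSINERSEN, 3, 3)
            if c.residues == ("A", "mC", "mU")
        ][:1]
        expanded = enumerate_base_losses(span, 1, NUSINERSEN)
        assert len(expanded) == 4  # original + one loss per position
        original = span[0]
        a_loss = next(
            c for c in expanded if c.losses and NUSINERSEN.residues[next(iter(c.losses))] == "A"
        )
        adenine = Formula.parse("C5H5N5")
        assert a_loss.formula == original.formula - adenine + Formula.parse("H2O")
        assert "MoeR" in a_loss.sequence

    def test_zero_losses_is_identity(self):
        base = enumerate_truncations(NUSINERSEN, 2, 3)
        assert enumerate_base_losses(base, 0, NUSINERSEN) == base

    def test_gg_loss_symmetry_groups_to_one_formula(self):
        gg = [c for c in enumerate_truncations(NUSINERSEN, 2, 2) if c.residues == ("G", "G")]
        expanded = enumerate_base_losses(gg, 1, NUSINERSEN)
        lost = [c for c in expanded if c.losses]
        assert len(lost) == 2
        groups = formula_groups(lost)
        assert len(groups) == 1
        assert sum(len(v) for v in groups.values()) == 2


class TestAdjacentRuns:
    @pytest.mark.parametrize(
        "composition,expected",
        [(["mU", "mC"], 4), (["G", "G"], 1), (["A", "A"], 1)],
    )
    def test_nusinersen_window_counts(self, composition, expected):
        assert count_adjacent_runs(NUSINERSEN, composition) == expected

    def test_window_longer_than_oligo_is_zero(self):
        short = random_oligo(["G", "G"])
        assert count_adjacent_runs(short, ["G", "G", "G"]) == 0

    def test_composition_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            count_adjacent_runs(NUSINERSEN, ["G"])


class TestLabels:
    def test_left_truncation_only(self):
        (candidate,) = [
            c for c in enumerate_truncations(NUSINERSEN, 2, 2) if c.span == (0, 2)
        ]
        assert (candidate.label.a, candidate.label.b) == (0, 16)
        assert canonical_label(candidate) == "3'N-16"

    def test_both_end_truncation(self):
        (candidate,) = [
            c for c in enumerate_truncations(NUSINERSEN, 3, 3) if c.span == (7, 10)
        ]
        assert (candidate.label.a, candidate.label.b) == (7, 8)
        assert canonical_label(candidate) == "5'N-7+3'N-8"

    def test_label_span_bijection(self):
        candidates = enumerate_truncations(NUSINERSEN, 1, 18, include_full=True)
        labels = {(c.label.a, c.label.b) for c in candidates}
        assert len(labels) == len(candidates)


class TestCandidateSpace:
    def test_default_space_size_and_dedup(self, candidate_space):
        # 48 spans x 4 terminal combos x (1 + span length) loss variants
        expected = 4 * sum(
            (18 - L + 1) * (1 + L) for L in (2, 3, 4)
        )
        assert len(candidate_space) == expected
        keys = {(c.span, c.terminals, c.losses) for c in candidate_space}
        assert len(keys) == len(candidate_space)

    def test_isobaric_grouping_partitions_space(self, candidate_space):
        groups = formula_groups(candidate_space)
        assert sum(len(v) for v in groups.values()) == len(candidate_space)

    def test_masses_match_independent_oracle(self, candidate_space):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        rng = random.Random(7)
        for candidate in rng.sample(candidate_space, 20):
            assert candidate.mass_monoisotopic == pytest.approx(
                pyteomics_mass.calculate_mass(formula=candidate.formula.hill()), abs=1e-3
            )
            assert candidate.mass_monoisotopic == pytest.approx(
                mass(candidate.formula), abs=1e-9
            )

    def test_sequence_string_roundtrip(self, candidate_space):
        rng = random.Random(11)
        for candidate in rng.sample(candidate_space, 25):
            residues, terminals = parse_candidate_sequence(candidate.sequence)
            expected_tokens = tuple(
                "MoeR" if pos in candidate.losses else code
                for pos, code in zip(range(*candidate.span), candidate.residues)
            )
            assert residues == expected_tokens
            assert terminals == candidate.terminals

    def test_frame_export_columns(self, candidate_space):
        frame = candidates_to_frame(candidate_space[:5])
        assert list(frame.columns)[:4] == ["span_start", "span_stop", "label", "sequence"]
        assert len(frame) == 5
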