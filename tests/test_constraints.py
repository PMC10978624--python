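"""Constraint geometry, feasible-space enumeration, and the duplication model."""

import itertools

import numpy as np
import pytest

from promiscuity import (
    FitnessModel,
    RelationClass,
    antagonism_mean,
    build_pairwise_constraints,
    count_feasible_spaces,
    dissimilarity_score,
    duplication_study,
    enumerate_feasible_spaces,
    frustrated_fraction,
    model_promiscuity_distribution,
    neutral_variability,
    optimize_ancestor,
    optimize_duplicate,
    space_from_letters,
)
from conftest import grid_oracle

A, B, C, D, E = RelationClass


def satisfies(cls, point, n=2):
    halfspaces = build_pairwise_constraints(cls, 0, 1, n)
    x = np.asarray(point)
    return all(a @ x <= b + 1e-12 for a, b in halfspaces)


class TestPairwiseGeometry:
    @pytest.mark.parametrize(
        "cls, admitted, rejected",
        [
            (A, (1.0, 0.0), (0.8, 0.8)),
            (D, (1.0, 0.5), (1.0, 0.0)),
            (E, (0.55, 0.5), (0.7, 0.5)),
        ],
    )
    def test_examples(self, cls, admitted, rejected):
        assert satisfies(cls, admitted)
        assert not satisfies(cls, rejected)

    @pytest.mark.parametrize("cls", list(RelationClass))
    def test_corner_semantics(self, cls):
        assert satisfies(cls, (0.0, 0.0))  # origin always feasible
        assert satisfies(cls, (1.0, 1.0)) == (cls in {C, D, E})
        assert satisfies(cls, (1.0, 0.0)) == (cls in {A, B, C})

    def test_symmetric_in_pair_order(self):
        for cls in RelationClass:
            hs_ij = build_pairwise_constraints(cls, 0, 2, 3)
            hs_ji = build_pairwise_constraints(cls, 2, 0, 3)
            sets1 = {tuple(np.append(a, b)) for a, b in hs_ij}
            sets2 = {tuple(np.append(a, b)) for a, b in hs_ji}
            assert sets1 == sets2

    def test_identical_indices_rejected(self):
        with pytest.raises(ValueError):
            build_pairwise_constraints(A, 1, 1, 3)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n, expected", [(2, 5), (3, 35), (4, 210), (5, 1001), (6, 3876), (7, 12650), (8, 35960)]
    )
    def test_space_counts(self, n, expected):
        assert count_feasible_spaces(n) == expected
        assert len(enumerate_feasible_spaces(n)) == expected

    def test_out_of_range(self):
        for n in (1, 9):
            with pytest.raises(ValueError):
                enumerate_feasible_spaces(n)

    def test_canonical_assignment_sorted_descending(self):
        for space in enumerate_feasible_spaces(3):
            scores = space.scores
            assert (np.diff(scores) <= 0).all()

    def test_origin_feasible_everywhere(self):
        for space in enumerate_feasible_spaces(3):
            assert space.contains(np.zeros(3))

    def test_deterministic_order(self):
        ids1 = [s.space_id for s in enumerate_feasible_spaces(3)]
        ids2 = [s.space_id for s in enumerate_feasible_spaces(3)]
        assert ids1 == ids2
        assert len(set(ids1)) == 35


class TestScores:
    def test_antagonism_mean(self):
        assert antagonism_mean(space_from_letters("AAA", 3)) == 1.0
        assert antagonism_mean(space_from_letters("EEE", 3)) == 0.0
        assert antagonism_mean(space_from_letters("ACE", 3)) == pytest.approx(0.5)

    def test_dissimilarity(self):
        assert dissimilarity_score(space_from_letters("DDD", 3)) == 0.0
        assert dissimilarity_score(space_from_letters("AEE", 3)) == pytest.approx(1.0)
        assert dissimilarity_score(space_from_letters("ABC", 3)) == pytest.approx(0.5)


class TestAncestor:
    def test_unconstrained_space_reaches_the_corner(self):
        result = optimize_ancestor(space_from_letters("CCC", 3))
        np.testing.assert_allclose(result.x, np.ones(3), atol=1e-6)
        assert result.frustration == pytest.approx(0.0, abs=1e-6)

    def test_all_strong_antagonism_balances(self):
        result = optimize_ancestor(space_from_letters("AAA", 3))
        np.testing.assert_allclose(result.x, np.full(3, 0.5), atol=1e-6)
        assert result.frustration == pytest.approx(0.5, abs=1e-6)

    def test_mixed_antagonism_synergism_space(self):
        result = optimize_ancestor(space_from_letters("AEE", 3))
        np.testing.assert_allclose(result.x, [0.5, 0.5, 0.6], atol=1e-6)
        assert result.frustration == pytest.approx(0.4667, abs=1e-4)


class TestDuplicates:
    def test_all_strong_antagonism(self):
        space = space_from_letters("AAA", 3)
        outcome = optimize_duplicate(space, 0)
        assert outcome.x_selected_star == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(outcome.reported_vector, [1.0, 0.0, 0.0], atol=1e-9)
        assert outcome.duplicate_promiscuity == pytest.approx(0.0, abs=1e-9)
        assert outcome.gain == pytest.approx(0.5, abs=1e-6)

    def test_frustrated_space_remains_promiscuous(self):
        space = space_from_letters("AEE", 3)
        outcome = optimize_duplicate(space, 0)
        assert outcome.x_selected_star == pytest.approx(0.6, abs=1e-9)
        np.testing.assert_allclose(outcome.reported_vector, [0.6, 0.4, 0.5], atol=1e-9)
        assert outcome.duplicate_frustration == pytest.approx(0.4, abs=1e-9)
        assert outcome.duplicate_promiscuity == pytest.approx(0.988, abs=1e-3)

    def test_all_strong_synergism_cannot_shed_activities(self):
        space = space_from_letters("EEE", 3)
        outcome = optimize_duplicate(space, 0)
        assert outcome.x_selected_star == pytest.approx(1.0, abs=1e-9)
        assert outcome.neutral_ranges[1][0] == pytest.approx(0.9, abs=1e-9)
        assert outcome.neutral_ranges[2][0] == pytest.approx(0.9, abs=1e-9)
        assert outcome.gain == pytest.approx(0.0, abs=1e-6)
        assert outcome.duplicate_promiscuity == pytest.approx(0.999, abs=1e-3)

    def test_joint_neutral_minimum_variant_is_feasible(self):
        space = space_from_letters("AEE", 3)
        outcome = optimize_duplicate(space, 0, joint_neutral_minimum=True)
        assert space.contains(outcome.reported_vector, tol=1e-6)


class TestVariability:
    def test_unconstrained_ranges_span_the_box(self):
        space = space_from_letters("CCC", 3)
        ranges = neutral_variability(space, 0, 1.0)
        for low, high in ranges.values():
            assert low == pytest.approx(0.0, abs=1e-9)
            assert high == pytest.approx(1.0, abs=1e-9)

    def test_pinned_neutrals_in_frustrated_space(self):
        space = space_from_letters("AEE", 3)
        ranges = neutral_variability(space, 0, 0.6)
        assert ranges[1] == pytest.approx((0.4, 0.4), abs=1e-8)
        assert ranges[2] == pytest.approx((0.5, 0.5), abs=1e-8)

    def test_antagonism_forces_neutrals_to_zero(self):
        space = space_from_letters("AAA", 3)
        ranges = neutral_variability(space, 0, 1.0)
        assert ranges[1] == pytest.approx((0.0, 0.0), abs=1e-8)
        assert ranges[2] == pytest.approx((0.0, 0.0), abs=1e-8)


class TestGridOracleAgreement:
    def test_all_35_spaces_match_exhaustive_grid_search(self):
        for space in enumerate_feasible_spaces(3):
            oracle = grid_oracle(space, step=0.05)
            ancestor = optimize_ancestor(space)
            np.testing.assert_allclose(
                ancestor.x, oracle["ancestor"], atol=0.051,
                err_msg=f"ancestor mismatch in {space.space_id}",
            )
            for r in range(3):
                outcome = optimize_duplicate(space, r, ancestor=ancestor)
                ref = oracle["duplicates"][r]
                assert outcome.x_selected_star == pytest.approx(ref["x_r_star"], abs=0.051)
                for q, (lo, hi) in outcome.neutral_ranges.items():
                    assert lo == pytest.approx(ref["ranges"][q][0], abs=0.051)
                    assert hi == pytest.approx(ref["ranges"][q][1], abs=0.051)


@pytest.fixture(scope="module")
def study3():
    return duplication_study(3)


class TestStudy:

    def test_row_count_and_determinism(self, study3):
        assert len(study3) == 105
        assert study3.equals(duplication_study(3))

    def test_gain_non_negative_and_feasible_optima(self, study3):
        assert (study3["gain"] >= 0).all()
        assert study3["duplicate_promiscuity"].between(0, 1).all()

    def test_antagonism_correlates_with_gain(self, study3):
        r = np.corrcoef(study3["A_hat"], study3["gain"])[0, 1]
        assert r > 0.4

    def test_relaxing_a_constraint_never_hurts_the_duplicate(self):
        relaxations = {"E": "D", "D": "C", "A": "B", "B": "C"}
        for letters in itertools.combinations_with_replacement("ABCDE", 3):
            letters = "".join(letters)
            if letters[0] not in relaxations:
                continue
            relaxed = relaxations[letters[0]] + letters[1:]
            tight_space = space_from_letters(letters, 3)
            loose_space = space_from_letters(relaxed, 3)
            for r in range(3):
                tight = optimize_duplicate(tight_space, r)
                loose = optimize_duplicate(loose_space, r)
                assert loose.x_selected_star >= tight.x_selected_star - 1e-7

    def test_frustrated_fraction_values(self):
        assert frustrated_fraction(3) == 71
        assert frustrated_fraction(2) == 40

    def test_synergistic_spaces_never_frustrated(self):
        for letters in itertools.combinations_with_replacement("CDE", 3):
            space = space_from_letters("".join(letters), 3)
            assert optimize_ancestor(space).frustration < 1e-6

    def test_promiscuity_distribution_shape(self):
        values = model_promiscuity_distribution(3)
        assert len(values) == 105
        assert (values < 1e-9).any()         # full specialists exist
        assert (values > 0.98).any()         # irresolvably frustrated generalists exist
        low = (values < 0.1).sum()
        mid = ((values >= 0.45) & (values < 0.55)).sum()
        high = (values >= 0.9).sum()
        assert low > mid and high > mid
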