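"""PMC index computation: scores, grading, ranking, means, paths.

The bundled 10-policy table doubles as a worked example whose published
index table pins down the rounding convention (half-up to 2 decimals
before summation).
"""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmcindex import (
    GradeScale,
    PmcError,
    PrimaryScoreVector,
    ScoreTable,
    classify,
    evaluate_all,
    group_mean,
    improvement_path,
    pmc_index,
    primary_scores,
    variable_means,
)

EXPECTED_INDICES = {
    "P1": 8.67, "P2": 7.49, "P3": 7.35, "P4": 6.23, "P5": 7.07,
    "P6": 8.47, "P7": 6.91, "P8": 6.62, "P9": 7.94, "P10": 7.02,
}


def toy_table(schema, rows):
    """ScoreTable from {policy: 33-bit list} over the bundled schema."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(schema.secondary_ids))
    frame.index.name = "policy"
    return ScoreTable(schema, frame)


class TestPrimaryScores:
    def test_timeliness_score_of_first_policy(self, table):
        vec = primary_scores(table, "P1", mode="rounded2")
        assert vec.scores[2] == 0.67  # bits (1,1,0) -> 2/3 rounded half-up

    def test_exact_mode_keeps_fractions(self, table):
        vec = primary_scores(table, "P1", mode="exact")
        assert vec.fractions[2] == Fraction(2, 3)

    def test_all_ones_policy(self, schema):
        t = toy_table(schema, {"Q": [1] * 33})
        assert primary_scores(t, "Q").scores == (1.0,) * 9

    def test_three_quarters_either_mode(self, schema):
        bits = [1] * 33
        # Policy Tool (X9) holds the last 4 bits; pattern (1,0,1,1) -> 0.75
        bits[-4:] = [1, 0, 1, 1]
        t = toy_table(schema, {"Q": bits})
        assert primary_scores(t, "Q", "rounded2").scores[8] == 0.75
        assert primary_scores(t, "Q", "exact").fractions[8] == Fraction(3, 4)

    def test_unknown_policy(self, table):
        with pytest.raises(KeyError):
            primary_scores(table, "nope")


class TestPmcIndex:
    @pytest.mark.parametrize("policy,expected", sorted(EXPECTED_INDICES.items()))
    def test_rounded_mode_reproduces_published_indices(self, table, policy, expected):
        assert pmc_index(primary_scores(table, policy, "rounded2")) == expected

    @pytest.mark.parametrize(
        "policy,expected", [("P2", 7.48), ("P7", 6.90), ("P9", 7.93)]
    )
    def test_exact_mode_differs_where_rounding_is_load_bearing(
        self, table, policy, expected
    ):
        assert pmc_index(primary_scores(table, policy, "exact")) == expected

    def test_all_zero_vector(self):
        vec = PrimaryScoreVector("Z", (Fraction(0),) * 9)
        assert pmc_index(vec) == 0.0

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(PmcError):
            PrimaryScoreVector("Z", (Fraction(3, 2),) * 9)


class TestClassify:
    @pytest.mark.parametrize(
        "value,label",
        [
            (7.49, "Focused"),
            (6.23, "Weak applicability"),
            (7.50, "Focused"),  # right-closed boundary
            (6.50, "Weak applicability"),
            (6.51, "Focused"),
            (9.00, "Reasonable and Complete"),
            (0.00, "Weak applicability"),
        ],
    )
    def test_default_scale(self, value, label):
        assert classify(value) == label

    def test_negative_index_rejected(self):
        with pytest.raises(PmcError):
            classify(-0.1)

    def test_scale_invariants(self):
        with pytest.raises(PmcError):
            GradeScale(breakpoints=(7.5, 6.5))
        with pytest.raises(PmcError):
            GradeScale(breakpoints=(6.5,), labels=("a", "b", "c"))


class TestEvaluateAll:
    def test_ranking_order(self, results):
        by_rank = sorted(results, key=lambda r: r.rank)
        assert [r.policy for r in by_rank] == [
            "P1", "P6", "P9", "P2", "P3", "P5", "P10", "P7", "P8", "P4"
        ]

    def test_grade_counts(self, results):
        counts = {}
        for r in results:
            counts[r.grade] = counts.get(r.grade, 0) + 1
        assert counts == {
            "Reasonable and Complete": 3,
            "Focused": 6,
            "Weak applicability": 1,
        }

    def test_single_all_ones_policy(self, schema):
        t = toy_table(schema, {"Q": [1] * 33})
        (res,) = evaluate_all(t)
        assert (res.pmc_index, res.rank) == (9.0, 1)

    def test_empty_table_rejected(self, schema):
        empty = toy_table(schema, {})
        with pytest.raises(PmcError):
            evaluate_all(empty)


class TestMeans:
    def test_variable_means(self, results):
        assert variable_means(results) == (0.77, 1.0, 0.5, 0.77, 0.7, 1.0, 1.0, 0.84, 0.8)

    def test_identical_policies_mean_equals_their_scores(self, schema):
        bits = [1, 0, 1] * 4 + [1, 0, 1, 0, 1] + [1] * 4 + [0] * 3 + [1] * 5 + [0] * 4
        t = toy_table(schema, {"A": bits, "B": bits})
        res = evaluate_all(t)
        assert variable_means(res) == res[0].primary_scores.scores

    def test_overall_and_group_means(self, results, table):
        assert group_mean(results, table.policies) == 7.38
        assert group_mean(results, ["P3", "P4", "P5", "P6"]) == 7.28
        assert group_mean(results, ["P7", "P8", "P9", "P10"]) == 7.12

    def test_singleton_group(self, results):
        assert group_mean(results, ["P4"]) == 6.23

    def test_unknown_policy_in_subset(self, results):
        with pytest.raises(KeyError):
            group_mean(results, ["P1", "nope"])

    def test_empty_inputs_rejected(self, results):
        with pytest.raises(PmcError):
            variable_means([])
        with pytest.raises(PmcError):
            group_mean(results, [])


class TestImprovementPath:
    def test_tie_free_paths(self, by_policy, results):
        means = variable_means(results)
        assert improvement_path(by_policy["P3"], means) == (3, 1, 9, 8)
        assert improvement_path(by_policy["P4"], means) == (4, 9, 3, 1, 5, 8)

    def test_policy_at_or_above_mean_everywhere(self, by_policy, results):
        means = variable_means(results)
        assert improvement_path(by_policy["P1"], means) == ()


# ---------------------------------------------------------------------------
# properties

bit_rows = st.lists(st.integers(0, 1), min_size=33, max_size=33)


class TestProperties:
    @settings(max_examples=50, deadline=None)
    @given(bits=bit_rows, flip=st.integers(0, 32))
    def test_flipping_a_bit_up_never_decreases_the_index(self, schema_cached, bits, flip):
        schema = schema_cached
        t = toy_table(schema, {"Q": bits})
        before = pmc_index(primary_scores(t, "Q"))
        flipped = list(bits)
        flipped[flip] = 1
        t2 = toy_table(schema, {"Q": flipped})
        after = pmc_index(primary_scores(t2, "Q"))
        assert after >= before
        assert 0.0 <= after <= 9.0

    @settings(max_examples=50, deadline=None)
    @given(bits=bit_rows, seed=st.integers(0, 2**16))
    def test_permuting_criteria_within_a_primary_preserves_scores(
        self, schema_cached, bits, seed
    ):
        import random

        schema = schema_cached
        rng = random.Random(seed)
        permuted = list(bits)
        offset = 0
        for p in schema.primaries:
            chunk = permuted[offset : offset + p.n_secondaries]
            rng.shuffle(chunk)
            permuted[offset : offset + p.n_secondaries] = chunk
            offset += p.n_secondaries
        s1 = primary_scores(toy_table(schema, {"Q": bits}), "Q").scores
        s2 = primary_scores(toy_table(schema, {"Q": permuted}), "Q").scores
        assert s1 == s2


@pytest.fixture(scope="module")
def schema_cached(schema):
    return schema
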