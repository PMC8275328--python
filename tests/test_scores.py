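"""Variability scores: closed forms, oracles, invariants, ranking."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohortflow.model import Cohort, PatientRecord, derive_blocks
from cohortflow.scores import (
    coefficient_of_variation,
    modvr,
    rank_features,
    rate_of_change_categorical,
    rate_of_change_continuous,
    score_feature,
    unalikeability,
    variance_score,
)
from cohortflow.synth import (
    CategoricalFeatureSpec,
    EventSpec,
    SyntheticCohortConfig,
    generate_synthetic_cohort,
)

from conftest import make_feature


def pair_fraction_oracle(values):
    """Brute-force fraction of unequal ordered pairs (self-pairs included)."""
    n = len(values)
    return sum(a != b for a in values for b in values) / (n * n)


class TestModVR:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (["A", "A", "A"], 0.0),
            (["A", "B", "C", "D"], 1.0),
            (["A", "A", "B", "C"], 0.75),  # K=3, n=4, f_m=2 -> 3*2/(4*2)
        ],
    )
    def test_closed_forms(self, values, expected):
        assert modvr(values) == pytest.approx(expected)

    def test_fewer_than_two_observations_is_missing(self):
        assert modvr(["A"]) is None
        assert modvr(["A", None]) is None

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=2, max_size=40))
    def test_bounds_and_extremes(self, values):
        s = modvr(values)
        assert 0.0 <= s <= 1.0
        if len(set(values)) == 1:
            assert s == 0.0
        counts = {c: values.count(c) for c in set(values)}
        uniform = len(set(counts.values())) == 1 and len(counts) >= 2
        assert (s == 1.0) == uniform


class TestUnalikeability:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (["A", "A", "A", "A"], 0.0),
            (["A", "A", "B", "B"], 0.5),
            (["A", "A", "B", "C"], 0.625),
        ],
    )
    def test_closed_forms(self, values, expected):
        assert unalikeability(values) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=2, max_size=50))
    def test_equals_unequal_pair_fraction(self, values):
        assert unalikeability(values) == pytest.approx(pair_fraction_oracle(values))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from("ABCD"), min_size=2, max_size=40))
    def test_bounded_below_one(self, values):
        k = len(set(values))
        assert 0.0 <= unalikeability(values) <= 1.0 - 1.0 / k + 1e-12


class TestNumericScores:
    def test_cv_examples(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(0.5)
        assert coefficient_of_variation([0, 0, 0]) is None  # zero mean

    def test_cv_negative_mean_absolute(self):
        assert coefficient_of_variation([-2, -4, -6]) == pytest.approx(0.5)

    def test_variance_examples(self):
        assert variance_score([1, 1]) == 0.0
        assert variance_score([2, 4, 6]) == pytest.approx(4.0)
        assert variance_score([3]) is None


class TestRateOfChange:
    @pytest.mark.parametrize(
        "series,expected",
        [
            (["II", "II", "IV"], 0.5),
            (["A", "A", "A", "A"], 0.0),
            (["A", "B", "A"], 1.0),
        ],
    )
    def test_categorical(self, series, expected):
        assert rate_of_change_categorical(series) == pytest.approx(expected)

    def test_pairs_spanning_gap_excluded(self):
        assert rate_of_change_categorical(["A", None, "B"]) is None
        assert rate_of_change_categorical(["A", None, "B", "B"]) == 0.0

    @pytest.mark.parametrize(
        "series,rng,expected",
        [
            ([0, 5, 10], 10, 0.5),
            ([7, 7, 7], 10, 0.0),
            ([0, 10], 10, 1.0),
        ],
    )
    def test_continuous(self, series, rng, expected):
        assert rate_of_change_continuous(series, rng) == pytest.approx(expected)

    def test_zero_range_scores_zero(self):
        assert rate_of_change_continuous([3, 3], 0) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10))
    def test_continuous_bounded_by_range(self, series):
        span = max(series) - min(series)
        s = rate_of_change_continuous(series, span if span else 1.0)
        assert 0.0 <= s <= 1.0 + 1e-12


def _two_tp_cohort(values_t0, values_t1, datatype="categorical"):
    n = len(values_t0)
    patients = [
        PatientRecord(f"P{i}", [(f"P{i}_S0", 0), (f"P{i}_S1", 100)]) for i in range(n)
    ]
    cohort = Cohort(patients=patients)
    values = {}
    for i in range(n):
        values[f"P{i}_S0"] = values_t0[i]
        values[f"P{i}_S1"] = values_t1[i]
    cohort.add_feature(make_feature("f", datatype, values))
    return cohort


class TestScoreFeature:
    def test_constant_feature_scores_zero_everywhere(self):
        cohort = _two_tp_cohort(["A"] * 5, ["A"] * 5)
        grid = derive_blocks(cohort, ["f"])
        for score, agg in [("modvr", "min"), ("modvr", "max"),
                           ("unalikeability", "mean"), ("rate_of_change", "mean")]:
            assert score_feature(cohort, grid, "f", score, agg) == 0.0

    def test_row_aggregation_max(self):
        # tp0 is A,A,B,C (ModVR 0.75); tp1 constant (ModVR 0)
        cohort = _two_tp_cohort(["A", "A", "B", "C"], ["A"] * 4)
        grid = derive_blocks(cohort, ["f"])
        assert score_feature(cohort, grid, "f", "modvr", "max") == pytest.approx(0.75)
        assert score_feature(cohort, grid, "f", "modvr", "min") == 0.0
        assert score_feature(cohort, grid, "f", "modvr", "mean") == pytest.approx(0.375)

    def test_datatype_mismatch_errors(self):
        cohort = _two_tp_cohort([1.0, 2.0], [3.0, 4.0], datatype="continuous")
        grid = derive_blocks(cohort, ["f"])
        with pytest.raises(ValueError, match="not defined for continuous"):
            score_feature(cohort, grid, "f", "modvr", "max")

    def test_row_scores_invariant_under_patient_reordering(self):
        cohort = _two_tp_cohort(["A", "A", "B", "C"], ["A", "B", "B", "C"])
        perm = Cohort(patients=[cohort.patients[i] for i in (2, 0, 3, 1)])
        perm.add_feature(cohort.features["f"])
        for c in (cohort, perm):
            grid = derive_blocks(c, ["f"])
            assert score_feature(c, grid, "f", "modvr", "mean") == pytest.approx(
                score_feature(cohort, derive_blocks(cohort, ["f"]), "f", "modvr", "mean")
            )
            assert score_feature(c, grid, "f", "rate_of_change", "mean") == pytest.approx(
                score_feature(cohort, derive_blocks(cohort, ["f"]), "f",
                              "rate_of_change", "mean")
            )


class TestOrthogonalVariabilityPatterns:
    """High-within/zero-across vs zero-within/high-across constructions."""

    def test_within_timepoint_variability_only(self):
        rng = random.Random(7)
        t0 = list("ABCD") * 250  # exactly uniform within the timepoint
        rng.shuffle(t0)
        cohort = _two_tp_cohort(t0, list(t0))  # per-patient constant series
        grid = derive_blocks(cohort, ["f"])
        assert score_feature(cohort, grid, "f", "rate_of_change", "mean") == 0.0
        assert score_feature(cohort, grid, "f", "modvr", "min") == pytest.approx(1.0, abs=0.02)

    def test_across_timepoint_variability_only(self):
        n = 50
        cohort = _two_tp_cohort(["A"] * n, ["B"] * n)  # uniform rows, switching columns
        grid = derive_blocks(cohort, ["f"])
        assert score_feature(cohort, grid, "f", "modvr", "max") == 0.0
        assert score_feature(cohort, grid, "f", "rate_of_change", "mean") == 1.0


class TestMarkovRecovery:
    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5])
    def test_mean_rate_of_change_recovers_switch_probability(self, p):
        cfg = SyntheticCohortConfig(
            n_patients=200,
            timepoint_weights={4: 1.0},
            categorical_features=[CategoricalFeatureSpec(
                name="state", categories=("A", "B", "C"),
                distribution=(1 / 3, 1 / 3, 1 / 3), switch_probability=p)],
            event=EventSpec(occurrence_probability=0.0),
            seed=11,
        )
        cohort, _ = generate_synthetic_cohort(cfg)
        grid = derive_blocks(cohort, ["state"])
        estimate = score_feature(cohort, grid, "state", "rate_of_change", "mean")
        n_transitions = 200 * 3
        se = np.sqrt(p * (1 - p) / n_transitions)
        if p == 0.0:
            assert estimate == 0.0
        else:
            assert abs(estimate - p) <= 3 * se


class TestRanking:
    def test_dominant_feature_ranks_first(self):
        cohort = _two_tp_cohort(["A", "A", "B", "C"], ["A", "B", "C", "C"])
        g = {f"P{i}_S0": "X" for i in range(4)} | {f"P{i}_S1": "X" for i in range(4)}
        cohort.add_feature(make_feature("const", "categorical", g))
        grid = derive_blocks(cohort, ["f", "const"])
        table = rank_features(cohort, grid, [("modvr", "max")])
        assert table.rank_of("f", "modvr_max") == 1
        assert table.rank_of("const", "modvr_max") == 2

    def test_single_feature_ranks_first(self):
        cohort = _two_tp_cohort(["A", "B"], ["A", "B"])
        grid = derive_blocks(cohort, ["f"])
        table = rank_features(cohort, grid, [("modvr", "mean")])
        assert table.rank_of("f", "modvr_mean") == 1

    def test_missing_scores_rank_last(self):
        cohort = _two_tp_cohort(["A", "A", "B", "C"], ["A", "B", "C", "C"])
        mc = {f"P{i}_S0": float(i) for i in range(4)} | {f"P{i}_S1": float(i * 2) for i in range(4)}
        cohort.add_feature(make_feature("mc", "continuous", mc))
        grid = derive_blocks(cohort, ["f", "mc"])
        table = rank_features(cohort, grid, [("modvr", "max")])
        assert table.rank_of("mc", "modvr_max") == 2  # inapplicable -> missing -> last

    def test_metadata_columns_present(self):
        cohort = _two_tp_cohort(["A", "B"], ["B", "A"])
        grid = derive_blocks(cohort, ["f"])
        table = rank_features(cohort, grid, [("unalikeability", "mean")])
        for col in ("feature_id", "name", "datatype", "source", "domain"):
            assert col in table.table.columns

    def test_empty_requests_rejected(self):
        cohort = _two_tp_cohort(["A", "B"], ["B", "A"])
        grid = derive_blocks(cohort, ["f"])
        with pytest.raises(ValueError, match="at least one"):
            rank_features(cohort, grid, [])
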