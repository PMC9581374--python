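"""Interestingness measures: printed formulas, identities and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

import discrimint.metrics as dmm
from discrimint import (
    ContingencyCounts,
    DataMatrix,
    OutcomeVector,
    Pattern,
    UndefinedMetric,
    UsageError,
    assess,
    best_class_by_lift,
    evaluate_counts,
    threshold_flags,
    worked_example_fixture,
)


def random_counts(rng, n_max=300):
    n = int(rng.integers(2, n_max))
    f = int(rng.integers(0, n + 1))
    g = int(rng.integers(0, n + 1))
    a = int(rng.integers(max(0, f + g - n), min(f, g) + 1))
    return ContingencyCounts(n, f, g, a)


@st.composite
def counts_strategy(draw):
    n = draw(st.integers(2, 300))
    f = draw(st.integers(1, n))
    g = draw(st.integers(1, n))
    a = draw(st.integers(max(0, f + g - n), min(f, g)))
    return ContingencyCounts(n, f, g, a)


class TestBasicMeasures:
    @pytest.mark.parametrize(
        "counts, expected",
        [((9, 3, 4, 3), 1.0), ((9, 3, 4, 0), 0.0), ((100, 20, 30, 15), 0.75)],
    )
    def test_confidence(self, counts, expected):
        assert dmm.confidence(ContingencyCounts(*counts)) == expected

    @pytest.mark.parametrize(
        "counts, expected",
        [((100, 20, 30, 6), 1.0), ((9, 3, 4, 3), 2.25)],
    )
    def test_lift(self, counts, expected):
        assert dmm.lift(ContingencyCounts(*counts)) == pytest.approx(expected)

    def test_universal_consequent_lift_reduces_to_confidence(self):
        counts = ContingencyCounts(50, 10, 50, 7)
        assert dmm.lift(counts) == pytest.approx(dmm.confidence(counts))

    def test_undefined_on_empty_antecedent(self):
        counts = ContingencyCounts(10, 0, 4, 0)
        with pytest.raises(UndefinedMetric):
            dmm.confidence(counts)
        values, undefined = evaluate_counts(counts)
        assert values["Confidence"] is None
        assert "Confidence" in undefined

    @settings(max_examples=200, derandomize=True)
    @given(counts_strategy())
    def test_lift_equals_confidence_over_consequent_rate(self, counts):
        expected = dmm.confidence(counts) / (counts.n_consequent / counts.n_total)
        assert dmm.lift(counts) == pytest.approx(expected)

    def test_independence_zeroes_all_dependence_measures(self):
        counts = ContingencyCounts(100, 20, 30, 6)  # a*N == f*g
        assert dmm.lift(counts) == 1.0
        assert dmm.chi_squared(counts) == 0.0
        assert dmm.information_gain(counts) == 0.0
        assert dmm.gini_index(counts) == 0.0


class TestChiSquared:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 100:
            c = random_counts(rng)
            n, f, g, a = c.as_tuple()
            if f in (0, n) or g in (0, n):
                continue
            table = [[a, f - a], [g - a, n - f - g + a]]
            expected = chi2_contingency(np.array(table) + 0.0, correction=False)[0]
            assert dmm.chi_squared(c) == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_perfect_association_equals_n(self):
        for n, k in [(10, 3), (50, 20)]:
            assert dmm.chi_squared(ContingencyCounts(n, k, k, k)) == pytest.approx(n)

    def test_zero_expected_cell_undefined(self):
        with pytest.raises(UndefinedMetric):
            dmm.chi_squared(ContingencyCounts(10, 10, 4, 4))


class TestSplitMeasures:
    def test_perfect_balanced_split(self):
        counts = ContingencyCounts(10, 5, 5, 5)
        assert dmm.information_gain(counts) == pytest.approx(1.0)
        assert dmm.gini_index(counts) == pytest.approx(0.5)

    @pytest.mark.parametrize("counts", [(10, 0, 4, 0), (10, 10, 4, 4)])
    def test_degenerate_split_yields_zero(self, counts):
        c = ContingencyCounts(*counts)
        assert dmm.information_gain(c) == 0.0
        assert dmm.gini_index(c) == 0.0

    def test_unit_interval_metrics_stay_in_bounds(self):
        rng = np.random.default_rng(43)
        bounded = (
            "Rule Support",
            "Coverage (Support)",
            "Confidence",
            "All-Confidence",
            "Standardised Lift",
            "Information Gain",
            "Gini Index",
            "Hyper Confidence",
        )
        for _ in range(2000):
            values, _ = evaluate_counts(random_counts(rng))
            for name in bounded:
                v = values[name]
                if v is not None:
                    assert 0.0 <= v <= 1.0, name
            for name in ("Lift", "Chi-Squared"):
                if values[name] is not None:
                    assert values[name] >= 0.0


class TestStandardisedLift:
    def test_attainability_extremes_by_enumeration(self):
        rng = np.random.default_rng(47)
        for _ in range(200):
            n = int(rng.integers(3, 200))
            f = int(rng.integers(1, n))
            g = int(rng.integers(1, n))
            a_min, a_max = max(0, f + g - n), min(f, g)
            values = []
            for a in range(a_min, a_max + 1):
                try:
                    values.append(
                        dmm.standardised_lift(ContingencyCounts(n, f, g, a))
                    )
                except UndefinedMetric:
                    values.append(None)
            if values[-1] is not None:
                assert values[-1] == pytest.approx(1.0)
            if values[0] is not None:
                assert values[0] == pytest.approx(0.0, abs=1e-12)
            assert all(v is None or 0.0 <= v <= 1.0 for v in values)


class TestSupportFamily:
    def test_hand_arithmetic(self):
        c = ContingencyCounts(9, 3, 4, 3)
        assert dmm.all_confidence(c) == 0.75
        assert dmm.laplace_confidence(c) == pytest.approx(0.8)
        assert dmm.casual_support(c) == pytest.approx((3 + 9 - 3 - 4 + 3) / 9)
        assert dmm.difference_in_support(c) == pytest.approx(3 / 4 - 0 / 5)
        assert dmm.bigger_support(c) == pytest.approx(0.75)

    def test_perfect_rule_descriptive_confirmed_confidence(self):
        c = ContingencyCounts(20, 6, 6, 6)
        assert dmm.descriptive_confirmed_confidence(c) == 1.0
        assert dmm.casual_confidence(c) == 1.0

    def test_hyper_confidence_matches_explicit_summation(self):
        rng = np.random.default_rng(53)
        for _ in range(30):
            c = random_counts(rng, n_max=80)
            n, f, g, a = c.as_tuple()
            expected = sum(
                math.comb(g, k) * math.comb(n - g, f - k) / math.comb(n, f)
                for k in range(max(0, f + g - n), a + 1)
            )
            assert dmm.hyper_confidence(c) == pytest.approx(expected, abs=1e-10)

    def test_hyper_lift_quantile_denominator(self):
        c = ContingencyCounts(100, 20, 30, 15)
        q99 = stats.hypergeom.ppf(0.99, 100, 30, 20)
        assert dmm.hyper_lift(c) == pytest.approx(15 / q99)


class TestStatisticalSignificance:
    def make(self, col):
        frame = pd.DataFrame({"y1": col})
        outcome = OutcomeVector("numerical", np.arange(len(col), dtype=float))
        return DataMatrix(frame, outcome)

    def test_single_column_matches_direct_binomial_summation(self):
        col = ["a"] * 7 + ["b"] * 3
        matrix = self.make(col)
        pattern = Pattern(descriptor=(("y1", "a"),))
        counts = ContingencyCounts(10, 7, 5, 4)
        p = 0.7
        expected = sum(
            math.comb(10, k) * p**k * (1 - p) ** (10 - k) for k in range(7, 11)
        )
        got = dmm.statistical_significance(matrix, pattern, counts)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_full_coverage_tail_is_p_to_the_n(self):
        # marginal frequency p = 0.8 < 1, full coverage f = N
        matrix = self.make(["a"] * 8 + ["b", "b"])
        pattern = Pattern(descriptor=(("y1", "a"),))
        counts = ContingencyCounts(10, 10, 5, 5)
        assert dmm.statistical_significance(
            matrix, pattern, counts
        ) == pytest.approx(0.8**10)

    def test_over_expected_pattern_is_not_significant(self):
        # pattern expected in ~90% of rows but observed in only 2
        col = ["a"] * 9 + ["b"]
        matrix = self.make(col)
        pattern = Pattern(descriptor=(("y1", "a"),))
        counts = ContingencyCounts(10, 2, 5, 1)
        assert dmm.statistical_significance(matrix, pattern, counts) > 0.99

    def test_rows_only_pattern_is_undefined(self):
        matrix = self.make(["a"] * 5)
        pattern = Pattern(rows=frozenset({0, 1}))
        with pytest.raises(UndefinedMetric):
            dmm.statistical_significance(
                matrix, pattern, ContingencyCounts(5, 2, 2, 1)
            )


class TestThresholdFlags:
    def test_reference_row_logic_on_straddling_values(self):
        just_above = {
            "Information Gain": 0.61,
            "Gini Index": 0.61,
            "Chi-Squared": 3.85,
            "Lift": 1.31,
            "Standardised Lift": 0.61,
            "Statistical Significance": 0.049,
        }
        assert all(threshold_flags(just_above).values())
        just_below = {
            "Information Gain": 0.6,
            "Gini Index": 0.6,
            "Chi-Squared": 3.84,
            "Lift": 1.3,
            "Standardised Lift": 0.6,
            "Statistical Significance": 0.05,
        }
        assert not any(threshold_flags(just_below).values())

    def test_flags_none_for_undefined_metrics(self):
        flags = threshold_flags({"Lift": None})
        assert flags["Lift"] is None


def categorical_matrix():
    frame = pd.DataFrame(
        {
            "y1": ["a", "a", "a", "b", "b", "b", "c", "c", "c"],
            "y2": ["x", "x", "y", "x", "y", "y", "x", "y", "x"],
        }
    )
    outcome = OutcomeVector(
        "categorical",
        np.array(["u", "u", "u", "v", "v", "w", "w", "v", "u"], dtype=object),
    )
    return DataMatrix(frame, outcome)


class TestBestClass:
    def test_pure_coverage_selects_its_class(self):
        matrix = categorical_matrix()
        pattern = Pattern(descriptor=(("y1", "a"),))
        label, ra = best_class_by_lift(matrix, pattern)
        assert label == "u"
        assert ra.metrics["Confidence"] == 1.0

    def test_matches_exhaustive_per_class_enumeration(self):
        matrix = categorical_matrix()
        pattern = Pattern(descriptor=(("y2", "x"),))
        label, _ = best_class_by_lift(matrix, pattern)
        lifts = {}
        for lab in ("u", "v", "w"):
            n, f, g, a = dmm.build_contingency(matrix, pattern, lab).as_tuple()
            lifts[lab] = a * n / (f * g)
        assert lifts[label] == max(lifts.values())

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame({"y1": ["a", "b"]})
        matrix = DataMatrix(
            frame, OutcomeVector("categorical", np.array(["u", "u"], dtype=object))
        )
        with pytest.raises(UsageError):
            best_class_by_lift(matrix, Pattern(descriptor=(("y1", "a"),)))


class TestAssess:
    def test_worked_example_full_report(self):
        matrix, pattern = worked_example_fixture()
        (report,) = assess(matrix, [pattern], setup="empirical")
        (rule,) = report.rules
        assert rule.consequent_text == "[1.0,5.0]"
        assert rule.counts.as_tuple() == (5, 3, 4, 3)
        assert rule.metrics["Lift"] == pytest.approx(1.25)
        assert rule.metrics["Confidence"] == 1.0
        assert set(dmm.METRIC_REGISTRY) <= set(rule.metrics)
        assert rule.flags["Chi-Squared"] is not None

    def test_empty_pattern_list(self):
        matrix, _ = worked_example_fixture()
        assert assess(matrix, []) == []

    def test_empty_coverage_warns_instead_of_aborting(self):
        matrix, pattern = worked_example_fixture()
        ghost = Pattern(descriptor=(("y1", "zzz"),), label="ghost")
        reports = assess(matrix, [ghost, pattern], setup="min_max")
        assert reports[0].rules == [] and reports[0].warnings
        assert reports[1].rules  # batch continued

    def test_categorical_path_equals_binarized_numerical_path(self):
        matrix, pattern = worked_example_fixture()
        (num_report,) = assess(matrix, [pattern], setup="empirical")
        (num_rule,) = num_report.rules
        # binarize the outcome with the inferred interval and rerun as classes
        inside = num_rule.consequent.contains(matrix.outcome.values)
        cat = DataMatrix(
            matrix.predictors.copy(),
            OutcomeVector(
                "categorical",
                np.where(inside, "in", "out").astype(object),
            ),
        )
        (cat_report,) = assess(cat, [pattern])
        in_rule = next(
            r for r in cat_report.rules if r.consequent_text == "in"
        )
        assert in_rule.counts.as_tuple() == num_rule.counts.as_tuple()
        for name, value in num_rule.metrics.items():
            if value is None:
                assert in_rule.metrics[name] is None
            else:
                assert in_rule.metrics[name] == pytest.approx(value)

    def test_argmax_and_threshold_modes_shape_the_rule_list(self):
        outcomes = list(range(20))
        frame = pd.DataFrame(
            {"y1": ["a" if i in {1, 2, 3, 10} else "b" for i in range(20)]}
        )
        matrix = DataMatrix(
            frame, OutcomeVector("numerical", np.array(outcomes, dtype=float))
        )
        pattern = Pattern(descriptor=(("y1", "a"),), label="p")
        # force a two-interval consequent via explicit empirical dominance
        (argmax_rep,) = assess(matrix, [pattern], setup="empirical", mode="argmax")
        assert len(argmax_rep.rules) == 1
        (all_rep,) = assess(matrix, [pattern], setup="empirical", mode="all")
        assert len(all_rep.rules) == 1
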