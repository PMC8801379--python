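"""Confusion metrics, cohort weighting, correlations, rank/t tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crbflow.errors import InputError, UndefinedStatisticError
from crbflow.performance import (
    CohortMetrics,
    MetricValue,
    cohort_confusion_metrics,
    combine_weighted_metrics,
    mann_whitney_test,
    pearson_r2,
    two_sample_t_test,
)
from crbflow.reference import (
    REFERENCE_VALIDATION_COUNTS,
    reference_calls_tables,
    reference_cohort_metrics,
)


class TestCohortConfusionMetrics:
    def test_reference_counts_reproduce_published_per_cohort_values(self):
        calls, subjects = reference_calls_tables("coriell")
        cm = cohort_confusion_metrics(calls, subjects, "coriell")
        rcs = cm.metrics["rcs"]
        assert rcs["sensitivity"].value == pytest.approx(20 / 22)
        assert rcs["specificity"].value == 1.0
        assert rcs["accuracy"].value == pytest.approx(34 / 36)
        assert (rcs["accuracy"].numerator, rcs["accuracy"].denominator) == (34, 36)

    def test_missing_relatives_yield_na_not_zero(self):
        calls, subjects = reference_calls_tables("northwell")
        cm = cohort_confusion_metrics(calls, subjects, "northwell")
        assert cm.metrics["rcs"]["sensitivity"].value == pytest.approx(0.75)
        assert not cm.metrics["rcs"]["specificity"].available
        assert not cm.metrics["rcs"]["accuracy"].available

    def test_all_correct_gives_unit_metrics(self):
        subjects = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "cohort": ["x"] * 4,
                "group": [1, 1, 3, 3],
            }
        )
        calls = pd.DataFrame(
            {"subject_id": ["a", "b", "c", "d"], "rcs": [True, True, False, False]}
        )
        cm = cohort_confusion_metrics(calls, subjects, "x")
        for metric in ("sensitivity", "specificity", "accuracy"):
            assert cm.metrics["rcs"][metric].value == 1.0

    def test_group2_excluded_from_metrics(self):
        subjects = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "cohort": ["x"] * 6,
                "group": [1, 1, 2, 2, 3, 3],
            }
        )
        calls = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "rcs": [True, True, True, False, False, False],
            }
        )
        cm = cohort_confusion_metrics(calls, subjects, "x")
        assert cm.metrics["rcs"]["accuracy"].denominator == 4

    def test_cohort_without_labeled_subjects_warns_all_na(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "cohort": ["x"], "group": [2]}
        )
        calls = pd.DataFrame({"subject_id": ["a"], "rcs": [True]})
        with pytest.warns(UserWarning, match="no group-1"):
            cm = cohort_confusion_metrics(calls, subjects, "x")
        assert not cm.metrics["rcs"]["sensitivity"].available

    def test_accuracy_identity_holds(self):
        for cohort in REFERENCE_VALIDATION_COUNTS:
            calls, subjects = reference_calls_tables(cohort)
            cm = cohort_confusion_metrics(calls, subjects, cohort)
            for block in cm.metrics.values():
                sens, spec, acc = (
                    block["sensitivity"],
                    block["specificity"],
                    block["accuracy"],
                )
                if not (sens.available and spec.available):
                    continue
                expected = (
                    sens.value * sens.denominator + spec.value * spec.denominator
                ) / (sens.denominator + spec.denominator)
                assert acc.value == pytest.approx(expected)


class TestCombinedMetrics:
    def test_published_weighted_examples(self):
        combined = combine_weighted_metrics(reference_cohort_metrics())
        rcs_sens = combined.metrics["rcs"]["sensitivity"]
        assert rcs_sens.value == pytest.approx(0.91, abs=0.005)
        assert rcs_sens.numerator == pytest.approx(41.7, abs=0.05)
        assert rcs_sens.denominator == 46
        p53_spec = combined.metrics["p53"]["specificity"]
        assert p53_spec.value == pytest.approx(0.84, abs=0.005)
        assert p53_spec.numerator == pytest.approx(35.4, abs=0.05)
        assert p53_spec.denominator == 42

    def test_identical_metric_is_idempotent(self):
        cohorts = [
            CohortMetrics.from_counts("a", 10, {"rcs": {"sensitivity": (8, 10), "specificity": (5, 5)}}),
            CohortMetrics.from_counts("b", 4, {"rcs": {"sensitivity": (8, 10), "specificity": (5, 5)}}),
        ]
        combined = combine_weighted_metrics(cohorts)
        assert combined.metrics["rcs"]["sensitivity"].value == pytest.approx(0.8)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=50),  # N
                st.floats(min_value=0.0, max_value=1.0),  # metric value
            ),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_weighted_mean_within_bounds(self, data):
        cohorts = []
        for i, (n, v) in enumerate(data):
            cm = CohortMetrics(cohort=f"c{i}", n_total=n)
            cm.metrics["rcs"] = {
                "sensitivity": MetricValue(v, v * n, n),
                "specificity": MetricValue.na(),
                "accuracy": MetricValue.na(),
            }
            cohorts.append(cm)
        combined = combine_weighted_metrics(cohorts)
        values = [t[1] for t in data]
        got = combined.metrics["rcs"]["sensitivity"].value
        assert min(values) - 1e-12 <= got <= max(values) + 1e-12

    def test_metric_unavailable_everywhere_propagates_na(self):
        cm = CohortMetrics.from_counts("a", 4, {"rcs": {"sensitivity": (3, 4)}})
        combined = combine_weighted_metrics([cm])
        assert not combined.metrics["rcs"]["specificity"].available

    def test_render_formats(self):
        mv = MetricValue(41.7 / 46, 41.7, 46)
        assert mv.render() == "0.91 (41.7/46)"
        assert MetricValue.na().render() == "NA"
        assert MetricValue.from_counts(14, 14).render() == "1.00 (14/14)"


class TestPearson:
    def test_identity_and_anticorrelation(self):
        assert pearson_r2([1, 2, 3, 4], [1, 2, 3, 4])["r2"] == pytest.approx(1.0)
        out = pearson_r2([1, 2, 3], [6, 4, 2])
        assert out["r"] == pytest.approx(-1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.3, size=30)
        a = pearson_r2(x, y)
        b = pearson_r2(y, x)
        c = pearson_r2(3.0 * x + 7.0, y)
        assert a["r2"] == pytest.approx(b["r2"])
        assert a["r2"] == pytest.approx(c["r2"])

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r2([1, 1, 1], [1, 2, 3])

    def test_length_checks(self):
        with pytest.raises(InputError):
            pearson_r2([1, 2], [1, 2])
        with pytest.raises(InputError):
            pearson_r2([1, 2, 3], [1, 2])


def _enumerated_mw_p(a, b):
    """Independent oracle: exact two-sided p by full enumeration of
    rank assignments to the first group."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * len(b) / 2.0
    us = []
    for combo in combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum()
        us.append(r - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    p = min(1.0, 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
    return p


class TestMannWhitney:
    def test_hand_enumerated_example(self):
        out = mann_whitney_test([1, 2], [3, 4])
        assert out["U"] == 0.0
        assert out["p_two_sided"] == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        out = mann_whitney_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p_two_sided"] == pytest.approx(1.0)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1 = rng.integers(2, 5)
            n2 = rng.integers(2, 5)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            got = mann_whitney_test(a, b)["p_two_sided"]
            assert got == pytest.approx(_enumerated_mw_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_test([], [1, 2])

    def test_large_sample_approximation_reasonable(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1.2, 1, 60)
        assert mann_whitney_test(a, b)["p_two_sided"] < 1e-6


class TestTTest:
    def test_identical_groups(self):
        out = two_sample_t_test([1.0, 2.0], [1.0, 2.0])
        assert out["t"] == 0.0 and out["p_two_sided"] == 1.0

    def test_hand_computed_example(self):
        out = two_sample_t_test([1, 2, 3], [4, 5, 6])
        assert out["t"] == pytest.approx(-3.674, abs=1e-3)
        assert out["p_two_sided"] == pytest.approx(0.0214, abs=5e-4)
        assert out["df"] == 4

    def test_zero_variance_conventions(self):
        assert two_sample_t_test([2.0, 2.0], [2.0, 2.0])["p_two_sided"] == 1.0
        with pytest.raises(UndefinedStatisticError):
            two_sample_t_test([1.0, 1.0], [2.0, 2.0])

    def test_group_size_checks(self):
        with pytest.raises(InputError):
            two_sample_t_test([1.0], [1.0, 2.0])
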