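"""Threshold classification, proportion CIs, AUC and sample-size arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echointerchange import (
    ConfigurationError,
    ConfusionCounts,
    DegenerateDataError,
    InsufficientDataError,
    accuracy_metrics,
    confusion_at_cutoff,
    empirical_auc,
    metric_consistent_counts,
    round_half_up,
    sample_size_prevalence,
)


class TestConfusionAtCutoff:
    def test_basic_classification(self):
        c = confusion_at_cutoff([(35, 30), (55, 60)], cutoff=40)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_identical_test_and_reference_never_misclassify(self):
        pairs = [(v, v) for v in (20, 40, 41, 60, 80)]
        c = confusion_at_cutoff(pairs, cutoff=40)
        assert c.fp == 0 and c.fn == 0

    def test_boundary_is_positive_under_inclusive_rule(self):
        c = confusion_at_cutoff([(40, 45)], cutoff=40, inclusive=True)
        assert c.fp == 1

    def test_boundary_is_negative_under_strict_rule(self):
        c = confusion_at_cutoff([(40, 45)], cutoff=40, inclusive=False)
        assert c.tn == 1

    def test_empty_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            confusion_at_cutoff([], cutoff=40)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(5, 90), st.floats(5, 90)), min_size=1, max_size=60),
           st.floats(20, 60), st.floats(20, 60))
    def test_raising_cutoff_never_decreases_positives(self, pairs, c1, c2):
        lo, hi = sorted((c1, c2))
        a = confusion_at_cutoff(pairs, cutoff=lo)
        b = confusion_at_cutoff(pairs, cutoff=hi)
        assert b.tp + b.fp >= a.tp + a.fp


class TestAccuracyMetrics:
    def test_matches_printed_study_metrics(self):
        # the unique-accuracy solution family for the study's printed metrics
        s = accuracy_metrics(ConfusionCounts(tp=20, fp=20, fn=13, tn=392))
        assert round_half_up(s.accuracy.value, 2) == 0.93
        assert round_half_up(s.sensitivity.value, 2) == 0.61
        assert round_half_up(s.specificity.value, 2) == 0.95
        assert round_half_up(s.ppv.value, 2) == 0.50
        assert round_half_up(s.npv.value, 2) == 0.97

    def test_perfect_classifier(self):
        s = accuracy_metrics(ConfusionCounts(1, 0, 0, 1))
        for m in (s.accuracy, s.sensitivity, s.specificity, s.ppv, s.npv):
            assert m.value == 1.0

    def test_zero_denominator_reported_as_undefined(self):
        s = accuracy_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert s.sensitivity.value == 0.0
        assert s.npv.value == 0.5
        assert not s.ppv.defined and "denominator" in s.ppv.undefined_reason

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_agrees_with_per_formula_recomputation(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        s = accuracy_metrics(ConfusionCounts(tp, fp, fn, tn))
        total = tp + fp + fn + tn
        assert s.accuracy.value == pytest.approx((tp + tn) / total, abs=1e-12)
        if tp + fn:
            assert s.sensitivity.value == pytest.approx(tp / (tp + fn), abs=1e-12)
        if tn + fp:
            assert s.specificity.value == pytest.approx(tn / (tn + fp), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(1, 50))
    def test_wilson_ci_in_unit_interval_and_contains_estimate(self, k, extra):
        n = k + extra
        s = accuracy_metrics(ConfusionCounts(tp=k, fp=0, fn=n - k, tn=0))
        m = s.sensitivity
        assert 0 <= m.ci_low <= m.value <= m.ci_high <= 1

    def test_clopper_pearson_flag(self):
        wilson = accuracy_metrics(ConfusionCounts(20, 20, 13, 392))
        exact = accuracy_metrics(ConfusionCounts(20, 20, 13, 392), ci_method="beta")
        assert exact.sensitivity.ci_low != wilson.sensitivity.ci_low
        assert exact.sensitivity.ci_low <= exact.sensitivity.value <= exact.sensitivity.ci_high


def pairwise_auc(scores):
    """Exhaustive comparison over all (positive, negative) pairs."""
    pos = [s for s, y in scores if y]
    neg = [s for s, y in scores if not y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        scores = [(x, True) for x in (5, 6, 7)] + [(x, False) for x in (1, 2, 3)]
        auc, _ = empirical_auc(scores)
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        scores = [(1.0, True)] * 4 + [(1.0, False)] * 6
        auc, _ = empirical_auc(scores)
        assert auc == 0.5

    def test_worked_example_with_tie(self):
        # pairs: (3>1) + (3>2) + (2>1) + (2==2)/2 = 3.5 of 4
        auc, _ = empirical_auc([(3, True), (2, True), (1, False), (2, False)])
        assert auc == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            empirical_auc([(1.0, True), (2.0, True)])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 20), st.booleans()), min_size=2, max_size=200))
    def test_equals_exhaustive_pairwise_oracle(self, scores):
        labels = {y for _, y in scores}
        if labels != {True, False}:
            return
        auc, _ = empirical_auc(scores)
        assert auc == pytest.approx(pairwise_auc(scores), abs=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        y = rng.random(150) < 0.3
        x = rng.normal(0, 1, 150) + 1.2 * y
        auc, _ = empirical_auc(list(zip(x, y)))
        assert auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_delong_ci_contains_estimate(self):
        rng = np.random.default_rng(9)
        y = rng.random(120) < 0.4
        x = rng.normal(0, 1, 120) + y
        auc, (lo, hi) = empirical_auc(list(zip(x, y)), ci_method="delong")
        assert 0 <= lo <= auc <= hi <= 1


class TestMetricConsistentCounts:
    def test_perfect_targets_include_identity_table(self):
        sols = metric_consistent_counts({"sensitivity": 1.0, "specificity": 1.0}, total=2)
        assert ConfusionCounts(1, 0, 0, 1) in sols

    def test_impossible_targets_give_empty_list(self):
        assert metric_consistent_counts({"sensitivity": 0.99, "ppv": 0.01}, total=10) == []

    def test_solutions_actually_round_to_targets(self):
        targets = {"sensitivity": 0.8, "ppv": 0.67}
        for c in metric_consistent_counts(targets, total=30):
            assert round_half_up(c.tp / (c.tp + c.fn), 2) == 0.8
            assert round_half_up(c.tp / (c.tp + c.fp), 2) == 0.67


class TestSampleSize:
    @pytest.mark.parametrize(
        "p,margin,expected",
        [(0.10, 0.02, 864), (0.50, 0.05, 384), (0.10, 0.04, 216)],
    )
    def test_margin_of_error_arithmetic(self, p, margin, expected):
        assert sample_size_prevalence(p, margin) == expected

    def test_invalid_margin_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_size_prevalence(0.1, 1.0)
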