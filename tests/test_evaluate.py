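"""Split plans, error metrics, and the pairwise condition-ordering statistic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitpower.evaluate import (ORDERING_THRESHOLD, SplitPlan, compute_metrics,
                                ordering_accuracy, ordering_confusion,
                                plan_both_novel, plan_novel_condition,
                                plan_novel_subject, run_use_case)
from tests.conftest import make_trial


def _dummy_trials(n_subjects, n_conditions):
    return [make_trial(subject_id=f"S{s:02d}", condition_id=f"c{c}",
                       baseline=(c == 0))
            for s in range(n_subjects) for c in range(n_conditions)]


class TestSplitPlans:
    def test_novel_condition_holds_out_ten_percent(self):
        trials = _dummy_trials(6, 9)
        plan = plan_novel_condition(trials, frac=0.10, seed=5)
        assert len(plan.folds) == 6
        for train, test in plan.folds:
            assert len(test) == round(0.10 * 54) == 5
            assert not set(train) & set(test)
            assert len(train) + len(test) == 54

    def test_novel_condition_reproducible_and_validated(self):
        trials = _dummy_trials(4, 5)
        a = plan_novel_condition(trials, seed=3)
        b = plan_novel_condition(trials, seed=3)
        assert a.folds == b.folds
        with pytest.raises(ValueError):
            plan_novel_condition(trials, frac=0.0)

    @pytest.mark.parametrize("n_subjects", [6, 13])
    def test_novel_subject_is_loso(self, n_subjects):
        trials = _dummy_trials(n_subjects, 3)
        plan = plan_novel_subject(trials)
        assert len(plan.folds) == n_subjects
        test_union = [p for _, test in plan.folds for p in test]
        assert sorted(test_union) == sorted(
            (t.subject.subject_id, t.condition.condition_id) for t in trials)
        for _, test in plan.folds:
            assert len({s for s, _ in test}) == 1

    def test_both_novel_removes_conditions_everywhere(self):
        trials = _dummy_trials(6, 9)
        plan = plan_both_novel(trials, n_conditions=2, seed=1)
        assert len(plan.folds) == 6
        for train, test in plan.folds:
            assert len(test) == 2
            held_subject = {s for s, _ in test}
            held_conditions = {c for _, c in test}
            assert len(held_subject) == 1
            assert not {c for _, c in train} & held_conditions
            assert not {s for s, _ in train} & held_subject
        assert plan.folds == plan_both_novel(trials, n_conditions=2, seed=1).folds

    def test_overlapping_fold_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(use_case="novel_subject",
                      folds=[([("S0", "c0")], [("S0", "c0")])])


class TestMetrics:
    def test_perfect_predictions_score_zero(self):
        preds = [(350.0, 350.0, "S0", "c0"), (400.0, 400.0, "S0", "c1")]
        rep = compute_metrics(preds, {"S0": 70.0})
        assert rep.percent_error_mean == 0.0 and rep.rmse_per_kg == 0.0

    def test_percent_error_is_condition_mae_over_truth(self):
        preds = [(380.0, 400.0, "S0", "c0"), (420.0, 400.0, "S0", "c0")]
        rep = compute_metrics(preds, {"S0": 70.0})
        assert rep.percent_error_mean == pytest.approx(5.0)

    def test_rmse_normalized_by_mean_mass(self):
        preds = [(360.0, 350.0, "S0", "c0"), (340.0, 350.0, "S1", "c0")]
        rep = compute_metrics(preds, {"S0": 60.0, "S1": 80.0})
        assert rep.rmse_per_kg == pytest.approx(10.0 / 70.0, abs=1e-4)


def _enumerated_accuracy(est, truth, threshold):
    """Independent exhaustive pair enumeration of the three-way outcome rule."""
    def outcome(a, b):
        if abs(a - b) <= threshold * b:
            return 0
        return 1 if a > b else -1
    per_subject = []
    for s in est:
        conditions = sorted(est[s])
        pairs = list(itertools.combinations(conditions, 2))
        hits = sum(outcome(est[s][i], est[s][j]) == outcome(truth[s][i], truth[s][j])
                   for i, j in pairs)
        per_subject.append(100.0 * hits / len(pairs))
    return float(np.mean(per_subject))


class TestOrdering:
    def test_perfect_estimates_with_large_gaps_score_100(self):
        truth = {"S0": {"c0": 300.0, "c1": 400.0, "c2": 520.0}}
        assert ordering_accuracy(truth, truth) == 100.0

    def test_reverse_ranked_estimates_score_0(self):
        truth = {"S0": {"c0": 300.0, "c1": 400.0, "c2": 520.0}}
        est = {"S0": {"c0": 520.0, "c1": 400.0, "c2": 300.0}}
        assert ordering_accuracy(est, truth) == 0.0

    def test_within_threshold_pair_scored_by_rule(self):
        # Truths 10 W apart are "within" 4.2% of 310; estimates 100 W apart
        # are not, so the single pair is scored incorrect.
        truth = {"S0": {"c0": 300.0, "c1": 310.0}}
        est = {"S0": {"c0": 300.0, "c1": 400.0}}
        assert ordering_accuracy(est, truth) == 0.0

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 1000), k=st.integers(2, 5))
    def test_matches_exhaustive_enumeration(self, seed, k):
        rng = np.random.default_rng(seed)
        conditions = [f"c{i}" for i in range(k)]
        truth = {s: {c: float(rng.uniform(200, 600)) for c in conditions}
                 for s in ("S0", "S1")}
        est = {s: {c: float(rng.uniform(200, 600)) for c in conditions}
               for s in ("S0", "S1")}
        assert ordering_accuracy(est, truth) == pytest.approx(
            _enumerated_accuracy(est, truth, ORDERING_THRESHOLD))

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_common_positive_scaling(self, scale):
        truth = {"S0": {"c0": 300.0, "c1": 330.0, "c2": 500.0}}
        est = {"S0": {"c0": 310.0, "c1": 315.0, "c2": 480.0}}
        scaled = lambda m: {s: {c: v * scale for c, v in d.items()} for s, d in m.items()}
        assert ordering_accuracy(est, truth) == pytest.approx(
            ordering_accuracy(scaled(est), scaled(truth)))


class TestConfusion:
    TRUTH = {s: {"c0": 300.0, "c1": 400.0, "c2": 500.0} for s in ("S0", "S1")}

    def test_perfect_estimates_give_identity(self):
        np.testing.assert_array_equal(ordering_confusion(self.TRUTH, self.TRUTH),
                                      np.eye(3))

    def test_adjacent_swap_in_every_subject(self):
        est = {s: {"c0": 300.0, "c1": 500.0, "c2": 400.0} for s in ("S0", "S1")}
        mat = ordering_confusion(est, self.TRUTH)
        expected = np.eye(3)
        expected[[1, 2], [1, 2]] = 0.0
        expected[1, 2] = expected[2, 1] = 1.0
        np.testing.assert_array_equal(mat, expected)

    def test_rows_and_columns_sum_to_one(self):
        rng = np.random.default_rng(8)
        est = {s: {c: float(rng.uniform(100, 900)) for c in ("c0", "c1", "c2")}
               for s in ("S0", "S1")}
        mat = ordering_confusion(est, self.TRUTH)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0)

    def test_heterogeneous_condition_sets_rejected(self):
        est = {"S0": {"c0": 1.0, "c1": 2.0}, "S1": {"c0": 1.0, "cX": 2.0}}
        with pytest.raises(ValueError, match="same condition set"):
            ordering_confusion(est, est)


class TestRunUseCase:
    def test_loso_on_noisy_data_reports_all_metrics(self, realistic_assisted):
        trials, record = realistic_assisted
        rep = run_use_case(trials, plan_novel_subject(trials), model_kind="linear",
                           labels=dict(record.true_power))
        assert len(rep.fold_percent_errors) == 3
        assert rep.percent_error_mean > 0 and rep.rmse_per_kg > 0
        assert rep.ordering_percent is not None and 0 <= rep.ordering_percent <= 100
        assert rep.confusion is not None and rep.confusion.shape == (9, 9)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0)

    def test_empty_fold_rejected(self, realistic_assisted):
        trials, record = realistic_assisted
        plan = SplitPlan(use_case="novel_subject",
                         folds=[([(t.subject.subject_id, t.condition.condition_id)
                                  for t in trials], [("ghost", "c0")])])
        with pytest.raises(ValueError, match="no feature vectors"):
            run_use_case(trials, plan, labels=dict(record.true_power))
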