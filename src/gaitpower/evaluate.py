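"""Cross-validation use cases, error metrics, and condition-ordering statistics.

Three use cases probe how much subject- and condition-specific training data
the estimator needs:

* ``novel_condition`` — per fold, ~10% of all (subject, condition) pairs are
  held out at random, so the model has seen the test subjects under other
  conditions.
* ``novel_subject`` — leave-one-subject-out: every condition of one subject
  is estimated by a model trained on the remaining subjects.  Two variants
  reuse this plan: ``subject_vertical_force`` restricts inputs to vertical
  ground reaction forces plus EMG, ``raw_subject`` feeds unfiltered signals
  (EMG rectified only).
* ``both_novel`` — one subject held out together with a small set of
  condition ids removed from every subject's training data; only those
  conditions are estimated for the held-out subject.

Fold count always equals the subject count, and estimation accuracy is
averaged across folds.  Percent error per condition is the mean absolute
error of that condition's per-sample estimates scaled by its true power;
RMSE/MAE are normalized by the mean test-subject mass.  Ordering quality over
a subject's conditions is scored pairwise with a three-way outcome (greater /
within / less than a relative threshold of 4.2%, the uncertainty of shortened
two-minute respirometry) and summarized in a rank confusion matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import ChannelSubset, FeatureVector, assemble_features, compute_condition_labels
from .io_dataset import TrialRecording
from . import models as _models

logger = logging.getLogger(__name__)

__all__ = [
    "ORDERING_THRESHOLD",
    "SplitPlan",
    "EvaluationReport",
    "plan_novel_condition",
    "plan_novel_subject",
    "plan_both_novel",
    "plan_for_use_case",
    "compute_metrics",
    "ordering_accuracy",
    "ordering_confusion",
    "run_use_case",
]

#: Relative threshold below which two conditions count as metabolically equal.
ORDERING_THRESHOLD = 0.042

USE_CASES = ("novel_condition", "novel_subject", "both_novel",
             "subject_vertical_force", "raw_subject")

#: Channel subset / raw-processing toggles implied by each use case.
USE_CASE_VARIANTS: dict[str, tuple[ChannelSubset, bool]] = {
    "novel_condition": (ChannelSubset.ALL, False),
    "novel_subject": (ChannelSubset.ALL, False),
    "both_novel": (ChannelSubset.ALL, False),
    "subject_vertical_force": (ChannelSubset.VERTICAL_FORCE_PLUS_EMG, False),
    "raw_subject": (ChannelSubset.ALL, True),
}

Pair = tuple[str, str]  # (subject_id, condition_id)


@dataclass
class SplitPlan:
    """Cross-validation folds over (subject, condition) pairs."""

    use_case: str
    folds: list[tuple[list[Pair], list[Pair]]]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.use_case not in USE_CASES:
            raise ValueError(f"unknown use case {self.use_case!r}; choose from {USE_CASES}")
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test pairs overlap within a fold")


@dataclass
class EvaluationReport:
    """Metrics of one use-case run (or one fold of it)."""

    use_case: str
    percent_error_mean: float
    rmse_per_kg: float
    mae_per_kg: float
    r2_train: float | None = None
    ordering_percent: float | None = None
    confusion: np.ndarray | None = None
    per_condition_percent_error: dict[Pair, float] = field(default_factory=dict)
    fold_percent_errors: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "use_case": self.use_case,
            "percent_error_mean": self.percent_error_mean,
            "rmse_per_kg": self.rmse_per_kg,
            "mae_per_kg": self.mae_per_kg,
            "r2_train": self.r2_train,
            "ordering_percent": self.ordering_percent,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "fold_percent_errors": self.fold_percent_errors,
        }


def _dataset_pairs(trials: Sequence[TrialRecording]) -> list[Pair]:
    return [(t.subject.subject_id, t.condition.condition_id) for t in trials]


def _subjects(pairs: Sequence[Pair]) -> list[str]:
    return sorted({s for s, _ in pairs})


def plan_novel_condition(trials: Sequence[TrialRecording], frac: float = 0.10,
                         seed: int = 0) -> SplitPlan:
    """Hold out ``round(frac * n_pairs)`` random pairs per fold.

    Held-out conditions need not coincide across subjects; the fold count
    equals the subject count so all plans are comparable.
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    pairs = _dataset_pairs(trials)
    subjects = _subjects(pairs)
    per_subject = {s: sum(1 for p in pairs if p[0] == s) for s in subjects}
    if min(per_subject.values()) < 2:
        raise ValueError("novel-condition plan needs >= 2 conditions per subject")
    n_test = max(1, int(round(frac * len(pairs))))
    rng = np.random.default_rng(seed)
    folds = []
    for _ in subjects:
        test_idx = rng.choice(len(pairs), size=n_test, replace=False)
        test = [pairs[i] for i in sorted(test_idx)]
        train = [p for p in pairs if p not in set(test)]
        folds.append((train, test))
    return SplitPlan(use_case="novel_condition", folds=folds, seed=seed)


def plan_novel_subject(trials: Sequence[TrialRecording],
                       use_case: str = "novel_subject") -> SplitPlan:
    """Leave-one-subject-out.  ``use_case`` may name one of its variants."""
    if use_case not in ("novel_subject", "subject_vertical_force", "raw_subject"):
        raise ValueError(f"{use_case!r} is not a leave-one-subject-out use case")
    pairs = _dataset_pairs(trials)
    folds = []
    for s in _subjects(pairs):
        test = [p for p in pairs if p[0] == s]
        train = [p for p in pairs if p[0] != s]
        folds.append((train, test))
    return SplitPlan(use_case=use_case, folds=folds)


def plan_both_novel(trials: Sequence[TrialRecording], n_conditions: int = 2,
                    seed: int = 0) -> SplitPlan:
    """One subject out plus ``n_conditions`` condition ids removed everywhere.

    The test set is only those conditions of the held-out subject; the
    conditions are resampled per fold.
    """
    pairs = _dataset_pairs(trials)
    subjects = _subjects(pairs)
    rng = np.random.default_rng(seed)
    folds = []
    for s in subjects:
        own_conditions = sorted({c for sid, c in pairs if sid == s})
        if len(own_conditions) < n_conditions:
            raise ValueError(f"subject {s} has fewer than {n_conditions} conditions")
        held = set(rng.choice(own_conditions, size=n_conditions, replace=False))
        test = [(s, c) for c in sorted(held)]
        train = [p for p in pairs if p[0] != s and p[1] not in held]
        folds.append((train, test))
    return SplitPlan(use_case="both_novel", folds=folds, seed=seed)


def plan_for_use_case(use_case: str, trials: Sequence[TrialRecording],
                      seed: int = 0, frac: float = 0.10,
                      n_conditions: int = 2) -> SplitPlan:
    if use_case == "novel_condition":
        return plan_novel_condition(trials, frac=frac, seed=seed)
    if use_case == "both_novel":
        return plan_both_novel(trials, n_conditions=n_conditions, seed=seed)
    if use_case in USE_CASES:
        return plan_novel_subject(trials, use_case=use_case)
    raise ValueError(f"unknown use case {use_case!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(predictions: Sequence[tuple[float, float, str, str]],
                    masses: Mapping[str, float],
                    use_case: str = "novel_subject",
                    r2_train: float | None = None) -> EvaluationReport:
    """Errors over one set of per-sample predictions.

    ``predictions`` holds (y_hat, y_true, subject_id, condition_id) per
    sample.  Percent error is computed per condition as 100 * MAE / true
    power, then averaged over conditions; RMSE and MAE in W are divided by
    the mean mass of the subjects present.
    """
    if not predictions:
        raise ValueError("no predictions to score")
    by_condition: dict[Pair, list[tuple[float, float]]] = {}
    for y_hat, y_true, sid, cid in predictions:
        by_condition.setdefault((sid, cid), []).append((y_hat, y_true))
    per_condition: dict[Pair, float] = {}
    for key, vals in by_condition.items():
        arr = np.asarray(vals)
        true_power = arr[0, 1]
        per_condition[key] = 100.0 * np.abs(arr[:, 0] - arr[:, 1]).mean() / true_power
    all_arr = np.asarray([(p[0], p[1]) for p in predictions])
    resid = all_arr[:, 0] - all_arr[:, 1]
    mean_mass = float(np.mean([masses[s] for s in {p[2] for p in predictions}]))
    return EvaluationReport(
        use_case=use_case,
        percent_error_mean=float(np.mean(list(per_condition.values()))),
        rmse_per_kg=float(np.sqrt((resid ** 2).mean()) / mean_mass),
        mae_per_kg=float(np.abs(resid).mean() / mean_mass),
        r2_train=r2_train,
        per_condition_percent_error=per_condition)


def _pair_outcome(v_i: float, v_j: float, threshold: float) -> str:
    if abs(v_i - v_j) <= threshold * v_j:
        return "within"
    return "greater" if v_i > v_j else "less"


def ordering_accuracy(cond_estimates: Mapping[str, Mapping[str, float]],
                      cond_truths: Mapping[str, Mapping[str, float]],
                      threshold: float = ORDERING_THRESHOLD) -> float:
    """Percent of condition pairs whose three-way ordering outcome matches.

    For each subject and each ordered pair of conditions (i, j), i < j in
    condition-id order, the first value is classified as greater than, within,
    or less than ``threshold`` (relative to the second value); the estimated
    and true outcomes are compared.  Subject accuracies are averaged.
    """
    per_subject = []
    for subject, est in cond_estimates.items():
        truth = cond_truths[subject]
        conditions = sorted(est)
        if len(conditions) < 2 or sorted(truth) != conditions:
            raise ValueError(f"subject {subject}: need >= 2 conditions with matching ids")
        correct = total = 0
        for ci, cj in itertools.combinations(conditions, 2):
            est_outcome = _pair_outcome(est[ci], est[cj], threshold)
            true_outcome = _pair_outcome(truth[ci], truth[cj], threshold)
            correct += est_outcome == true_outcome
            total += 1
        per_subject.append(100.0 * correct / total)
    if not per_subject:
        raise ValueError("no subjects to score")
    return float(np.mean(per_subject))


def ordering_confusion(cond_estimates: Mapping[str, Mapping[str, float]],
                       cond_truths: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Rank confusion matrix: true rank (rows) vs estimated rank (columns).

    Every subject must share the same condition set.  Entry (r, c) counts the
    subjects for whom the condition at true rank r got estimated rank c,
    divided by the subject count; a perfect estimator yields the identity.
    """
    subjects = sorted(cond_estimates)
    condition_sets = {frozenset(cond_estimates[s]) for s in subjects}
    condition_sets |= {frozenset(cond_truths[s]) for s in subjects}
    if len(condition_sets) != 1:
        raise ValueError("ordering_confusion requires the same condition set for every subject")
    k = len(next(iter(condition_sets)))
    matrix = np.zeros((k, k))
    for s in subjects:
        conditions = sorted(cond_truths[s])
        true_vals = np.array([cond_truths[s][c] for c in conditions])
        est_vals = np.array([cond_estimates[s][c] for c in conditions])
        true_rank = np.argsort(np.argsort(true_vals, kind="stable"), kind="stable")
        est_rank = np.argsort(np.argsort(est_vals, kind="stable"), kind="stable")
        for r, c in zip(true_rank, est_rank):
            matrix[r, c] += 1.0
    return matrix / len(subjects)


# ---------------------------------------------------------------------------
# End-to-end use-case runner
# ---------------------------------------------------------------------------

def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _fit_predict(model_kind: str, X_train, y_train, X_test, cfg, fold_seed: int):
    if model_kind == "linear":
        model = _models.fit_linear(X_train, y_train)
        return _models.predict_linear(model, X_test), _models.predict_linear(model, X_train)
    if model_kind == "mlp":
        base = cfg or _models.NetworkConfig()
        from dataclasses import replace as _replace
        model = _models.fit_mlp(X_train, y_train, _replace(base, seed=fold_seed))
        return model.predict(X_test), model.predict(X_train)
    raise ValueError(f"unknown model kind {model_kind!r} (choose 'linear' or 'mlp')")


def run_use_case(trials: Sequence[TrialRecording], plan: SplitPlan,
                 model_kind: str = "linear", cfg=None,
                 labels: Mapping[Pair, float] | None = None,
                 features: Sequence[FeatureVector] | None = None,
                 ordering_threshold: float = ORDERING_THRESHOLD) -> EvaluationReport:
    """Cross-validate one use case end to end.

    Features are assembled once under the plan's channel subset and raw-mode
    flags (feature extraction is per-trial and fold-independent); each fold
    then fits on its training pairs and predicts its test pairs.  Callers
    evaluating several plans with the same subset/raw flags may pass the
    assembled ``features`` to avoid recomputation.  Percent error is averaged
    condition-first within folds, then across folds.  Ordering statistics are
    computed when the folds jointly estimate every condition of every subject
    (the novel-subject family).
    """
    if labels is None:
        labels = compute_condition_labels(trials)
    subset, raw_mode = USE_CASE_VARIANTS[plan.use_case]
    feats = (assemble_features(trials, labels, subset=subset, raw_mode=raw_mode)
             if features is None else features)
    masses = {t.subject.subject_id: t.subject.mass for t in trials}

    by_pair: dict[Pair, list[FeatureVector]] = {}
    for fv in feats:
        by_pair.setdefault((fv.subject_id, fv.condition_id), []).append(fv)

    def stack(pairs: Sequence[Pair]):
        rows = [fv for p in pairs for fv in by_pair.get(p, [])]
        if not rows:
            raise ValueError("fold has no feature vectors (empty fold?)")
        X = np.stack([fv.x for fv in rows])
        y = np.array([fv.y for fv in rows])
        meta = [(fv.subject_id, fv.condition_id) for fv in rows]
        return X, y, meta

    fold_reports: list[EvaluationReport] = []
    test_estimates: dict[Pair, list[float]] = {}
    base_seed = plan.seed if plan.seed is not None else 0
    for fold_id, (train_pairs, test_pairs) in enumerate(plan.folds):
        overlap = set(train_pairs) & set(test_pairs)
        assert not overlap, f"test leakage in fold {fold_id}: {overlap}"
        X_tr, y_tr, _ = stack(train_pairs)
        X_te, y_te, meta_te = stack(test_pairs)
        y_hat_te, y_hat_tr = _fit_predict(model_kind, X_tr, y_tr, X_te, cfg,
                                          fold_seed=base_seed + fold_id)
        preds = [(float(h), float(t), sid, cid)
                 for h, t, (sid, cid) in zip(y_hat_te, y_te, meta_te)]
        fold_reports.append(compute_metrics(preds, masses, use_case=plan.use_case,
                                            r2_train=_r2(y_tr, y_hat_tr)))
        for h, (sid, cid) in zip(y_hat_te, meta_te):
            test_estimates.setdefault((sid, cid), []).append(float(h))
        logger.info("%s fold %d/%d: %.2f%% error", plan.use_case, fold_id + 1,
                    len(plan.folds), fold_reports[-1].percent_error_mean)

    ordering = confusion = None
    all_pairs = set(_dataset_pairs(trials))
    if set(test_estimates) == all_pairs:
        est = {}
        truth = {}
        for (sid, cid), vals in test_estimates.items():
            est.setdefault(sid, {})[cid] = float(np.mean(vals))
            truth.setdefault(sid, {})[cid] = labels[(sid, cid)]
        ordering = ordering_accuracy(est, truth, threshold=ordering_threshold)
        if len({frozenset(v) for v in est.values()}) == 1:
            confusion = ordering_confusion(est, truth)

    per_condition: dict[Pair, float] = {}
    for rep in fold_reports:
        per_condition.update(rep.per_condition_percent_error)
    return EvaluationReport(
        use_case=plan.use_case,
        percent_error_mean=float(np.mean([r.percent_error_mean for r in fold_reports])),
        rmse_per_kg=float(np.mean([r.rmse_per_kg for r in fold_reports])),
        mae_per_kg=float(np.mean([r.mae_per_kg for r in fold_reports])),
        r2_train=float(np.mean([r.r2_train for r in fold_reports])),
        ordering_percent=ordering,
        confusion=confusion,
        per_condition_percent_error=per_condition,
        fold_percent_errors=[r.percent_error_mean for r in fold_reports])
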