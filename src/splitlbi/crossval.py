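"""Repeated stratified K-fold full cross-validation of the classifier.

Protocol: the cohort is split into K stratified folds; each fold is
predicted by a model trained on the other K-1 (standardization
statistics from the training folds only, checkpoint selected on an
inner stratified 80/20 split of the training folds); the K out-of-fold
prediction sets are pooled into one prediction per subject and scored.
The whole procedure repeats R times with fresh fold assignments and the
across-repeat mean and 95% t-interval of each metric is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .lbi import (
    ModelHyperparams,
    ModelState,
    Standardizer,
    fit_path,
    predict_proba,
    select_checkpoint,
)
from .operator import DifferenceOperator, build_difference_operator
from .simulate import CohortDataset

__all__ = [
    "FoldPlan",
    "CVRepeat",
    "CVResult",
    "make_folds",
    "run_cv",
    "binary_metrics",
    "roc_auc",
    "repeat_cv",
    "t_ci",
]

METRICS = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass
class FoldPlan:
    """Per-subject fold assignment for one repeat."""

    assignment: np.ndarray  # fold index per subject, 0..K-1
    K: int
    seed: int
    repeat: int = 0

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class CVRepeat:
    """Pooled out-of-fold predictions of one repeat."""

    proba: np.ndarray
    pred: np.ndarray
    labels: np.ndarray
    plan: FoldPlan
    fold_states: list[ModelState] = field(default_factory=list)
    fold_standardizers: list[Standardizer] = field(default_factory=list)
    per_fold_accuracy: list[float] = field(default_factory=list)

    def metrics(self) -> dict[str, float]:
        acc, sens, spec = binary_metrics(self.labels, self.pred)
        return {
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
            "auc": roc_auc(self.labels, self.proba),
        }


@dataclass
class CVResult:
    """Across-repeat summary: per-repeat metric table, mean and 95% CI."""

    repeats: list[CVRepeat]
    per_repeat: dict[str, np.ndarray]
    mean: dict[str, float]
    ci95: dict[str, tuple[float, float] | None]
    ci_flagged_absent: bool = False


def make_folds(labels: np.ndarray, K: int, seed: int, repeat: int = 0) -> FoldPlan:
    """Stratified partition into K folds, reproducible from the seed.

    K = N degenerates to leave-one-out (stratification is vacuous with
    single-subject folds); any other K above the smaller class count
    cannot be stratified and is rejected.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int), minlength=2)
    assignment = np.empty(len(labels), dtype=int)
    if K == len(labels):
        perm = np.random.default_rng(seed).permutation(len(labels))
        assignment[perm] = np.arange(len(labels))
        return FoldPlan(assignment, K, seed, repeat)
    if K > counts.min():
        raise ValueError(f"K={K} exceeds the smaller class count {counts.min()}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return FoldPlan(assignment, K, seed, repeat)


def t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float] | None:
    """Across-repeat t-interval: mean +/- t_{R-1,0.975} * sd / sqrt(R);
    None (flagged absent) when fewer than 2 values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return None
    mean = v.mean()
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return (float(mean - half), float(mean + half))


def _fit_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    D: DifferenceOperator,
    hyper: ModelHyperparams,
    inner_seed: int,
):
    """Standardize on the training fold, fit on its 80% subtrain, select
    the checkpoint on the 20% inner validation split."""
    std = Standardizer.fit(X_tr)
    Xs = std.transform(X_tr)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y_tr)),
        test_size=0.2,
        stratify=y_tr,
        random_state=inner_seed % (2**32),
    )
    path = fit_path(Xs[idx_tr], y_tr[idx_tr], D, hyper, Xs[idx_val], y_tr[idx_val])
    state = select_checkpoint(path, Xs[idx_val], y_tr[idx_val], use_cached=True)
    return state, std


def run_cv(
    dataset: CohortDataset,
    hyper: ModelHyperparams,
    plan: FoldPlan,
    D: DifferenceOperator | None = None,
    fold_hook=None,
    keep_models: bool = False,
) -> CVRepeat:
    """One repeat of K-fold full cross-validation.

    ``fold_hook(X_tr, y_tr, X_te, y_te, fold)`` may return modified
    ``(X_tr, X_te)`` — a diagnostics hook used e.g. by leakage canaries.
    """
    X, y = dataset.features, np.asarray(dataset.labels)
    if D is None:
        D = build_difference_operator(dataset.mask, hyper.rho)
    proba = np.full(len(y), np.nan)
    repeat = CVRepeat(proba, np.empty(len(y), dtype=int), y.copy(), plan)
    for fold in range(plan.K):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training folds for fold {fold} contain a single class")
        X_tr, X_te = X[tr], X[te]
        if fold_hook is not None:
            X_tr, X_te = fold_hook(X_tr, y[tr], X_te, y[te], fold)
        inner_seed = (plan.seed * 1000003 + plan.repeat * 9176 + fold) % (2**31)
        state, std = _fit_fold(X_tr, y[tr], D, hyper, inner_seed)
        proba[te] = predict_proba(state, std.transform(X_te))
        repeat.per_fold_accuracy.append(
            float(np.mean((proba[te] > 0.5).astype(int) == y[te]))
        )
        if keep_models:
            repeat.fold_states.append(state)
            repeat.fold_standardizers.append(std)
    assert not np.isnan(proba).any(), "every subject must be predicted exactly once"
    repeat.pred = (proba > 0.5).astype(int)
    return repeat


def binary_metrics(labels: np.ndarray, predicted: np.ndarray):
    """(accuracy, sensitivity, specificity) with AD=1 as positive class.

    A metric whose denominator class is absent is returned as NaN.
    """
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predicted.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    acc = (tp + tn) / labels.size
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal AUC (= normalized Mann-Whitney U, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def roc_points(labels: np.ndarray, scores: np.ndarray):
    """(FPR, TPR) pairs of the ROC curve, for plotting/export."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def repeat_cv(
    dataset: CohortDataset,
    hyper: ModelHyperparams,
    R: int = 10,
    K: int = 10,
    seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """R repeats of K-fold CV; mean and 95% t-interval across repeats."""
    D = build_difference_operator(dataset.mask, hyper.rho)
    repeats = []
    for r in range(R):
        plan = make_folds(dataset.labels, K, seed=(seed + 101 * r) % (2**31), repeat=r)
        repeats.append(run_cv(dataset, hyper, plan, D=D, keep_models=keep_models))
    per_repeat = {
        m: np.array([rep.metrics()[m] for rep in repeats]) for m in METRICS
    }
    mean = {m: float(v.mean()) for m, v in per_repeat.items()}
    ci = {m: t_ci(v) for m, v in per_repeat.items()}
    return CVResult(repeats, per_repeat, mean, ci, R < 2)


def bootstrap_ci(labels, scores, metric="auc", n_boot=2000, seed=0, level=0.95):
    """Percentile bootstrap CI on pooled predictions (alternative CI)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    vals = []
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb, sb = labels[idx], scores[idx]
        if len(np.unique(yb)) < 2:
            continue
        if metric == "auc":
            vals.append(roc_auc(yb, sb))
        else:
            acc, sens, spec = binary_metrics(yb, (sb > 0.5).astype(int))
            vals.append({"accuracy": acc, "sensitivity": sens, "specificity": spec}[metric])
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
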