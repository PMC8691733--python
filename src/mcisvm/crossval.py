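"""Repeated two-level nested stratified cross-validation.

The outer loop is leave-one-out: each subject is the held-out test case
exactly once per repetition, and the full pipeline — t-test feature filter,
z-score standardization, class-cost derivation and SVM fit — is refit from
scratch on the N-1 training subjects of every outer fold, so no held-out
subject can influence selection, scaling or tuning (leakage guard).

Within each outer fold an inner stratified k-fold loop (default k = 10)
over the training subjects picks the penalty parameter C from a grid by
mean balanced accuracy (ties go to the smallest C). The whole procedure is
repeated ``n_repeats`` times (default 10) with re-randomized inner fold
assignments; the deterministic leave-one-out outer assignment is identical
across repetitions, so repetitions differ only through the C selection.

Metrics treat decline (y = -1) as the event class: sensitivity, precision,
F1 and the precision-recall curve all quantify the ability to detect
decliners, whose scores are the negated SVM decision values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix, apply_standardizer, assemble_features, fit_standardizer
from .svm import (
    _fit_kernel,
    _sample_costs,
    class_cost_from_counts,
    fit_fold_model,
    predict,
    ttest_filter,
)
from .synthetic import AtlasDefinition, SubjectScan

__all__ = [
    "CVConfig",
    "FoldPlan",
    "CVReport",
    "make_fold_plan",
    "inner_select_C",
    "run_nested_cv",
    "run_nested_cv_matrix",
    "subgroup_eval",
    "confusion_metrics",
    "precision_recall_auc",
]

#: Canonical penalty grid: log-spaced powers of two, 2^-5 .. 2^15.
DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16))


@dataclass(frozen=True)
class CVConfig:
    """Knobs of the nested cross-validation procedure."""

    alpha: float = 0.01
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    inner_k: int = 10
    n_repeats: int = 10
    seed: int = 0
    t_variant: str = "student"


@dataclass(frozen=True)
class FoldPlan:
    """Outer leave-one-out + per-repetition inner stratified assignments.

    ``inner[rep][i]`` is an integer array of length N giving the inner fold
    id of every training subject of outer fold ``i`` (the held-out subject
    ``i`` itself is marked -1).
    """

    n_subjects: int
    n_repeats: int
    inner_k: int
    seed: int
    inner: tuple[tuple[np.ndarray, ...], ...]

    @property
    def outer_test_order(self) -> np.ndarray:
        return np.arange(self.n_subjects)


def _stratified_assignment(
    y: np.ndarray, rows: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold ids for ``rows``, stratified by class, sizes within +-1."""
    fold_of = np.full(y.shape[0], -1, dtype=np.int64)
    for cls in (1, -1):
        members = rows[y[rows] == cls]
        members = rng.permutation(members)
        for f, chunk in enumerate(np.array_split(members, k)):
            fold_of[chunk] = f
    return fold_of


def make_fold_plan(
    y: np.ndarray, n_repeats: int = 10, inner_k: int = 10, seed: int = 0
) -> FoldPlan:
    """Build the deterministic fold plan for a label vector."""
    y = np.asarray(y)
    N = y.shape[0]
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError("each class needs at least 2 subjects")
    if N < inner_k + 1:
        raise ValueError(f"N = {N} too small for inner_k = {inner_k}")

    inner: list[tuple[np.ndarray, ...]] = []
    for rep in range(n_repeats):
        per_outer: list[np.ndarray] = []
        for i in range(N):
            rng = np.random.default_rng(np.random.SeedSequence((seed, rep, i)))
            train = np.setdiff1d(np.arange(N), [i])
            per_outer.append(_stratified_assignment(y, train, inner_k, rng))
        inner.append(tuple(per_outer))
    return FoldPlan(
        n_subjects=N,
        n_repeats=n_repeats,
        inner_k=inner_k,
        seed=seed,
        inner=tuple(inner),
    )


def _class_recalls(y_true: np.ndarray, y_pred: np.ndarray) -> list[float]:
    recalls = []
    for cls in (1, -1):
        sel = y_true == cls
        if sel.any():
            recalls.append(float((y_pred[sel] == cls).mean()))
    return recalls


def inner_select_C(
    X: np.ndarray,
    y: np.ndarray,
    train_rows: np.ndarray,
    grid,
    inner_fold_of: np.ndarray,
    alpha: float = 0.01,
    t_variant: str = "student",
) -> float:
    """Pick C by mean balanced accuracy over the inner stratified folds.

    For every inner split the full fold-internal pipeline (t-test filter,
    standardizer, class costs, SVM) is refit on the inner training rows
    only. Splits whose training side has fewer than two members of either
    class are skipped. Ties are broken toward the smallest C.
    """
    grid = sorted(float(C) for C in grid)
    if not grid:
        raise ValueError("C grid must be non-empty")
    X = np.asarray(X)
    y = np.asarray(y)
    train_rows = np.asarray(train_rows)

    scores: dict[float, list[float]] = {C: [] for C in grid}
    fold_ids = np.unique(inner_fold_of[train_rows])
    for f in fold_ids:
        val_rows = train_rows[inner_fold_of[train_rows] == f]
        tr_rows = train_rows[inner_fold_of[train_rows] != f]
        if val_rows.size == 0:
            continue
        ytr = y[tr_rows]
        if min((ytr == 1).sum(), (ytr == -1).sum()) < 2:
            continue
        # empty selection degrades gracefully to an intercept-only fit
        mask = ttest_filter(X, y, tr_rows, alpha=alpha, variant=t_variant)
        Xs = X[:, mask.keep]
        std = fit_standardizer(Xs, tr_rows)
        Z_tr = apply_standardizer(std, Xs[tr_rows])
        Z_val = apply_standardizer(std, Xs[val_rows])
        cost = class_cost_from_counts(ytr)
        K = Z_tr @ Z_tr.T
        K_val = Z_val @ Z_tr.T
        yf = ytr.astype(np.float64)
        warm = None
        for C in grid:
            beta, b, _ = _fit_kernel(K, yf, _sample_costs(ytr, C, cost), warm_start=warm)
            warm = (beta, b)
            decision = K_val @ beta + b
            pred = np.where(decision >= 0.0, 1, -1)
            recalls = _class_recalls(y[val_rows], pred)
            scores[C].append(float(np.mean(recalls)))

    means = {C: (np.mean(v) if v else -np.inf) for C, v in scores.items()}
    best = max(means.values())
    for C in grid:  # ascending: ties resolve to the smallest C
        if means[C] == best:
            return C
    return grid[0]


@dataclass(frozen=True)
class CVReport:
    """Per-repetition, per-subject predictions plus derived metrics."""

    y_true: np.ndarray  # (N,)
    predictions: np.ndarray  # (n_repeats, N)
    decisions: np.ndarray  # (n_repeats, N)
    chosen_C: np.ndarray  # (n_repeats, N)
    subject_ids: tuple[str, ...]
    config: CVConfig

    @property
    def n_repeats(self) -> int:
        return self.predictions.shape[0]

    def per_repetition_metrics(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.n_repeats):
            m = confusion_metrics(self.y_true, self.predictions[rep])
            m["pr_auc"] = precision_recall_auc(self.y_true, -self.decisions[rep])[2]
            m["repetition"] = rep
            rows.append(m)
        return pd.DataFrame(rows).set_index("repetition")

    def mean_metrics(self) -> dict[str, float]:
        """Headline numbers: per-repetition metrics averaged over repetitions."""
        return self.per_repetition_metrics().mean(axis=0).to_dict()

    def pooled_metrics(self) -> dict[str, float]:
        """Metrics on all predictions pooled across repetitions."""
        truth = np.tile(self.y_true, self.n_repeats)
        pred = self.predictions.ravel()
        m = confusion_metrics(truth, pred)
        m["pr_auc"] = precision_recall_auc(truth, -self.decisions.ravel())[2]
        return m

    def confusion_matrix(self, rep: int = 0) -> np.ndarray:
        """2x2 counts [[TN, FP], [FN, TP]] with decline (-1) as event."""
        t, p = self.y_true, self.predictions[rep]
        tp = int(((t == -1) & (p == -1)).sum())
        fn = int(((t == -1) & (p == 1)).sum())
        fp = int(((t == 1) & (p == -1)).sum())
        tn = int(((t == 1) & (p == 1)).sum())
        return np.array([[tn, fp], [fn, tp]])

    def to_dict(self) -> dict:
        return {
            "config": {
                "alpha": self.config.alpha,
                "C_grid": list(self.config.C_grid),
                "inner_k": self.config.inner_k,
                "n_repeats": self.config.n_repeats,
                "seed": self.config.seed,
                "t_variant": self.config.t_variant,
            },
            "subject_ids": list(self.subject_ids),
            "y_true": self.y_true.tolist(),
            "predictions": self.predictions.tolist(),
            "decisions": self.decisions.tolist(),
            "chosen_C": self.chosen_C.tolist(),
            "mean_metrics": self.mean_metrics(),
            "pooled_metrics": self.pooled_metrics(),
        }


def run_nested_cv_matrix(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig = CVConfig(),
    subject_ids: tuple[str, ...] | None = None,
) -> CVReport:
    """Nested CV on a prebuilt feature matrix (rows = subjects)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    N = X.shape[0]
    plan = make_fold_plan(y, config.n_repeats, config.inner_k, config.seed)

    predictions = np.empty((config.n_repeats, N), dtype=np.int64)
    decisions = np.empty((config.n_repeats, N))
    chosen = np.empty((config.n_repeats, N))
    for rep in range(config.n_repeats):
        for i in range(N):
            train = np.setdiff1d(np.arange(N), [i])
            C = inner_select_C(
                X,
                y,
                train,
                config.C_grid,
                plan.inner[rep][i],
                alpha=config.alpha,
                t_variant=config.t_variant,
            )
            model = fit_fold_model(
                X, y, train, C, alpha=config.alpha, t_variant=config.t_variant
            )
            label, dec = predict(model, X[i])
            predictions[rep, i] = label
            decisions[rep, i] = dec
            chosen[rep, i] = C

    if subject_ids is None:
        subject_ids = tuple(f"row-{i}" for i in range(N))
    return CVReport(
        y_true=y.copy(),
        predictions=predictions,
        decisions=decisions,
        chosen_C=chosen,
        subject_ids=tuple(subject_ids),
        config=config,
    )


def run_nested_cv(
    cohort: list[SubjectScan],
    atlas: AtlasDefinition,
    modalities={"t1", "conn"},
    config: CVConfig = CVConfig(),
    features: FeatureMatrix | None = None,
) -> CVReport:
    """Assemble features for a cohort and run the nested CV."""
    if features is None:
        features = assemble_features(cohort, atlas, frozenset(modalities))
    y = np.array([s.label for s in cohort])
    return run_nested_cv_matrix(
        features.values, y, config, subject_ids=features.subject_ids
    )


def subgroup_eval(
    cohort: list[SubjectScan],
    atlas: AtlasDefinition,
    subtype: str,
    modalities={"t1", "conn"},
    config: CVConfig = CVConfig(),
) -> CVReport:
    """Re-run the identical procedure on one baseline-subtype subgroup.

    Class costs are recomputed from the subgroup's own counts inside every
    fold, exactly as for the full cohort.
    """
    subset = [s for s in cohort if s.baseline_subtype == subtype]
    labels = {s.label for s in subset}
    if labels != {1, -1}:
        raise ValueError(
            f"subgroup {subtype!r} must retain both outcome classes, has {sorted(labels)}"
        )
    return run_nested_cv(subset, atlas, modalities, config)


# ---------------------------------------------------------------------------
# metrics (event class = decline, y = -1)
# ---------------------------------------------------------------------------

def confusion_metrics(truth: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """Accuracy, balanced accuracy, sensitivity, specificity, precision,
    F1 and MCC for binary +-1 labels with decline (-1) as the event class.

    MCC is defined as 0 whenever a marginal of the confusion matrix is
    zero.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0 or truth.shape != predicted.shape:
        raise ValueError("truth and predicted must be equal-length, non-empty")
    bad = set(np.unique(np.concatenate([truth, predicted]))) - {1, -1}
    if bad:
        raise ValueError(f"labels must be +-1, found {sorted(bad)}")

    tp = float(((truth == -1) & (predicted == -1)).sum())
    fn = float(((truth == -1) & (predicted == 1)).sum())
    fp = float(((truth == 1) & (predicted == -1)).sum())
    tn = float(((truth == 1) & (predicted == 1)).sum())
    n = tp + fn + fp + tn

    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    balanced = 0.5 * (sensitivity + specificity)
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "accuracy": accuracy,
        "balanced_accuracy": balanced,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "mcc": float(mcc),
    }


def precision_recall_auc(
    truth: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stepwise precision-recall curve and its area for the decline class.

    ``scores`` must be oriented so that larger means more decline-like
    (i.e. the negated SVM decision value). Tied scores are grouped into a
    single threshold. The area is the precision-weighted sum of recall
    steps; for constant scores the curve has a single point and the area
    equals the event prevalence.

    Returns ``(precision, recall, auc)`` with recall increasing.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.shape != scores.shape or truth.size == 0:
        raise ValueError("truth and scores must be equal-length, non-empty")
    n_event = int((truth == -1).sum())
    if n_event == 0 or n_event == truth.size:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    is_event = (truth[order] == -1).astype(np.float64)
    cum_tp = np.cumsum(is_event)
    cum_pred = np.arange(1, truth.size + 1, dtype=np.float64)
    # keep only the last index of each tied-score group
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tp = cum_tp[last_of_group]
    npred = cum_pred[last_of_group]
    precision = tp / npred
    recall = tp / n_event
    # area: sum precision * (recall step), steps from recall 0
    steps = np.diff(np.r_[0.0, recall])
    auc = float(np.sum(precision * steps))
    return precision, recall, auc
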