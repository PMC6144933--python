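"""Confusion counting, Sn/Sp/Acc/MCC, ROC/AUC, repeated 10-fold CV.

Metric conventions follow the class-total parameterisation: with N⁺, N⁻ the
positive (ncDNA) and negative (cDNA) totals and N₋⁺, N₊⁻ the cross-class
errors (positives called negative, negatives called positive):

    Sn  = 1 − N₋⁺/N⁺
    Sp  = 1 − N₊⁻/N⁻
    Acc = 1 − (N₋⁺ + N₊⁻)/(N⁺ + N⁻)
    MCC = [1 − (N₋⁺/N⁺ + N₊⁻/N⁻)]
          / sqrt[(1 + (N₊⁻ − N₋⁺)/N⁺)(1 + (N₋⁺ − N₊⁻)/N⁻)]

These are algebraically identical to the textbook TP/TN/FP/FN forms under
TP = N⁺ − N₋⁺, TN = N⁻ − N₊⁻, FN = N₋⁺, FP = N₊⁻ (MCC = phi coefficient).
When the MCC denominator vanishes (an empty predicted or actual class) the
value is defined as 0.

The cross-validation protocol partitions the data into stratified folds of
near-equal size; each fold is tested once against a model trained on the
rest. Confusion counts are pooled over the folds of one repeat
(micro-averaging), metrics computed per repeat, then averaged over repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import SVMConfig, build_estimator, grid_search
from .kmer_features import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tallies in class-total form."""

    n_pos: int  # N⁺: actual positives
    n_neg: int  # N⁻: actual negatives
    false_neg: int  # N₋⁺: positives predicted negative
    false_pos: int  # N₊⁻: negatives predicted positive

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg < 1:
            raise ValueError("need at least one sample")
        if not 0 <= self.false_neg <= self.n_pos:
            raise ValueError("false_neg out of range")
        if not 0 <= self.false_pos <= self.n_neg:
            raise ValueError("false_pos out of range")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.n_pos + other.n_pos,
            self.n_neg + other.n_neg,
            self.false_neg + other.false_neg,
            self.false_pos + other.false_pos,
        )


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None


def confusion_counts(
    truth: TypingSequence[int] | np.ndarray, predicted: TypingSequence[int] | np.ndarray
) -> ConfusionCounts:
    """Tally a prediction against truth; labels are +1 (ncDNA) / -1 (cDNA)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1 or truth.size == 0:
        raise ValueError("truth and predicted must be equal-length 1-D, non-empty")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        if not set(np.unique(arr)) <= {-1, 1}:
            raise ValueError(f"{name} labels must be +1 or -1")
    return ConfusionCounts(
        n_pos=int(np.sum(truth == 1)),
        n_neg=int(np.sum(truth == -1)),
        false_neg=int(np.sum((truth == 1) & (predicted == -1))),
        false_pos=int(np.sum((truth == -1) & (predicted == 1))),
    )


def metrics(counts: ConfusionCounts, auc: float | None = None) -> Metrics:
    """Sn/Sp/Acc/MCC from confusion counts (see module docstring).

    Sn (Sp) is undefined without actual positives (negatives) and raises;
    a vanishing MCC denominator yields 0 with a warning.
    """
    n_pos, n_neg = counts.n_pos, counts.n_neg
    fn, fp = counts.false_neg, counts.false_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("Sn/Sp need at least one sample of each class")
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    denom_sq = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    numer = 1.0 - (fn / n_pos + fp / n_neg)
    if denom_sq <= 0.0:
        # an entire predicted class is empty (or the product degenerates)
        warnings.warn("MCC denominator is zero; defining MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = numer / math.sqrt(denom_sq)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc)


# ---------------------------------------------------------------------------
# ROC / AUC from decision scores
# ---------------------------------------------------------------------------


def roc_auc(
    scores: TypingSequence[float] | np.ndarray,
    truth: TypingSequence[int] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """ROC points over score thresholds (ties grouped) and trapezoid AUC.

    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (FPR, TPR) pairs from (0, 0) to (1, 1). The trapezoid AUC over
    tie-grouped thresholds equals the normalized Mann–Whitney U statistic
    (ties counted half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present in truth")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth == 1)
    fps = np.cumsum(sorted_truth == -1)
    # keep only the last index of each tied-score run (ties grouped)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Repeated stratified k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldDetail:
    repeat: int
    fold: int
    counts: ConfusionCounts


@dataclass
class CVResult:
    """Averaged metrics plus per-repeat and per-fold detail."""

    metrics: Metrics
    per_repeat: list[Metrics]
    per_fold: list[FoldDetail]
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    tuned_params: list[tuple[float, float]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            (r + 1, m.sn, m.sp, m.acc, m.mcc, m.auc)
            for r, m in enumerate(self.per_repeat)
        ]
        rows.append(("mean", *[getattr(self.metrics, f) for f in
                               ("sn", "sp", "acc", "mcc", "auc")]))
        return pd.DataFrame(rows, columns=["repeat", "Sn", "Sp", "Acc", "MCC", "AUC"])


def make_folds(
    labels: np.ndarray,
    folds: int,
    seed: int,
    stratified: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs for one repeat; stratified by default."""
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=folds, shuffle=True, random_state=seed)
    X_dummy = np.zeros((labels.shape[0], 1))
    return [
        (train.copy(), test.copy()) for train, test in splitter.split(X_dummy, labels)
    ]


def _scores_for(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=np.float64)
    proba = est.predict_proba(X)
    pos_col = int(np.where(est.classes_ == 1)[0][0])
    return proba[:, pos_col] - 0.5


def cross_validate(
    dataset: LabeledDataset,
    spec: str = "svm",
    config: SVMConfig | None = None,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    stratified: bool = True,
    tune: bool = False,
    shared_folds: list[list[tuple[np.ndarray, np.ndarray]]] | None = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one classifier spec.

    Each repeat partitions the data afresh (seeded); every fold is held out
    once against a model trained on the remainder. Confusion counts and
    decision scores are pooled within a repeat, metrics (including pooled
    AUC) computed per repeat, then averaged across repeats. With
    ``tune=True`` a (C, γ) grid search runs inside every training fold
    (RBF-SVM only). ``shared_folds`` lets several specs see identical
    partitions for paired comparison.
    """
    if min(dataset.n_pos, dataset.n_neg) < folds:
        raise ValueError(
            f"each class must have >= folds samples "
            f"(n_pos={dataset.n_pos}, n_neg={dataset.n_neg}, folds={folds})"
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X, y = dataset.matrix, dataset.labels
    per_repeat: list[Metrics] = []
    per_fold: list[FoldDetail] = []
    assignments: list[np.ndarray] = []
    tuned: list[tuple[float, float]] = []
    for rep in range(repeats):
        folds_rep = (
            shared_folds[rep]
            if shared_folds is not None
            else make_folds(y, folds, seed + rep, stratified)
        )
        assignment = np.full(y.shape[0], -1, dtype=np.int64)
        rep_counts: ConfusionCounts | None = None
        pooled_scores = np.zeros(y.shape[0])
        for fold_id, (train_idx, test_idx) in enumerate(folds_rep):
            assignment[test_idx] = fold_id
            fold_config = config
            if tune:
                if spec != "svm":
                    raise ValueError("grid-search tuning applies to the SVM only")
                train_subset = LabeledDataset(
                    X[train_idx], y[train_idx], dataset.feature_names, dataset.k,
                    [dataset.record_ids[i] for i in train_idx],
                )
                gs = grid_search(train_subset, config, seed=seed + rep)
                base = config or SVMConfig()
                fold_config = SVMConfig(
                    C=gs.C, gamma=gs.gamma,
                    C_grid=base.C_grid, gamma_grid=base.gamma_grid,
                    inner_folds=base.inner_folds,
                )
                tuned.append((gs.C, gs.gamma))
            est = build_estimator(spec, fold_config, seed=seed + rep)
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            pooled_scores[test_idx] = _scores_for(est, X[test_idx])
            counts = confusion_counts(y[test_idx], pred)
            per_fold.append(FoldDetail(rep, fold_id, counts))
            rep_counts = counts if rep_counts is None else rep_counts + counts
        _, rep_auc = roc_auc(pooled_scores, y)
        per_repeat.append(metrics(rep_counts, auc=rep_auc))
        assignments.append(assignment)
    mean = Metrics(
        sn=float(np.mean([m.sn for m in per_repeat])),
        sp=float(np.mean([m.sp for m in per_repeat])),
        acc=float(np.mean([m.acc for m in per_repeat])),
        mcc=float(np.mean([m.mcc for m in per_repeat])),
        auc=float(np.mean([m.auc for m in per_repeat])),
    )
    return CVResult(mean, per_repeat, per_fold, assignments, tuned)


def compare_classifiers(
    dataset: LabeledDataset,
    specs: TypingSequence[str],
    config: SVMConfig | None = None,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> pd.DataFrame:
    """Paired comparison: every spec is cross-validated on identical folds.

    Returns a table (one row per spec) sorted by decreasing accuracy.
    """
    if len(specs) == 0:
        raise ValueError("need at least one classifier spec")
    shared = [
        make_folds(dataset.labels, folds, seed + rep, stratified)
        for rep in range(repeats)
    ]
    rows = []
    for spec in specs:
        res = cross_validate(
            dataset, spec, config, folds=folds, repeats=repeats, seed=seed,
            stratified=stratified, shared_folds=shared,
        )
        m = res.metrics
        rows.append((spec, m.sn, m.sp, m.acc, m.mcc, m.auc))
    table = pd.DataFrame(rows, columns=["classifier", "Sn", "Sp", "Acc", "MCC", "AUC"])
    return table.sort_values("Acc", ascending=False).reset_index(drop=True)
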