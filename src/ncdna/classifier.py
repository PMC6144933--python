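"""RBF-SVM training with C/γ grid search, baseline classifiers, persistence.

The working classifier is a support vector machine with the radial basis
function kernel K(x, y) = exp(−γ‖x−y‖²); the penalty C and kernel width γ
are chosen by exhaustive grid search over the canonical powers-of-two
ranges, scored by stratified inner cross-validation accuracy. k-mer
frequencies already live in [0, 1], so no additional feature scaling is
applied.

Decision-score sign convention: score > 0 → ncDNA (positive class); a score
of exactly 0 is called cDNA.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence as TypingSequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .kmer_features import (
    COMBINED,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    FeatureVector,
    LabeledDataset,
)

_MODEL_FORMAT_VERSION = 1

#: Baseline classifier names accepted by :func:`baseline_classifiers`.
BASELINE_SPECS = ("knn", "naive-bayes", "random-forest", "decision-tree")

#: All classifier spec names (the SVM plus the baselines).
CLASSIFIER_SPECS = ("svm",) + BASELINE_SPECS


def _default_c_grid() -> tuple[float, ...]:
    return tuple(2.0 ** e for e in range(-5, 16, 2))  # 2^-5 .. 2^15


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0 ** e for e in range(-15, 4, 2))  # 2^-15 .. 2^3


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters and grid-search space.

    ``C`` and ``gamma`` are the values used when no search is run; the grids
    are the canonical LIBSVM-style powers of two. ``inner_folds`` is the
    stratified CV depth used to score each grid point.
    """

    C: float = 1.0
    gamma: float = 1.0 / 256.0
    C_grid: tuple[float, ...] = field(default_factory=_default_c_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        for name, grid in (("C_grid", self.C_grid), ("gamma_grid", self.gamma_grid)):
            if len(grid) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(g <= 0 for g in grid):
                raise ValueError(f"{name} entries must be positive")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class ModelArtifact:
    """A fitted classifier plus the encoding contract it was trained under.

    ``feature_names`` fixes the expected probe dimension and column order;
    :func:`predict` refuses anything else.
    """

    estimator: object
    spec: str
    k: int | str
    feature_names: list[str]
    config: SVMConfig | None
    n_pos: int
    n_neg: int
    seed: int | None = None
    retained_features: list[str] | None = None
    trained_at: str = ""


def _validate_dataset(dataset: LabeledDataset) -> None:
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isfinite(dataset.matrix)):
        raise ValueError("training matrix contains non-finite values")


def train_svm(dataset: LabeledDataset, config: SVMConfig | None = None) -> ModelArtifact:
    """Fit an RBF-SVM with the config's C and γ. Deterministic given inputs."""
    config = config or SVMConfig()
    _validate_dataset(dataset)
    est = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    est.fit(dataset.matrix, dataset.labels)
    return ModelArtifact(
        estimator=est,
        spec="svm",
        k=dataset.k,
        feature_names=list(dataset.feature_names),
        config=config,
        n_pos=dataset.n_pos,
        n_neg=dataset.n_neg,
        trained_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


@dataclass(frozen=True)
class GridSearchResult:
    C: float
    gamma: float
    accuracy: float
    table: pd.DataFrame  # columns: C, gamma, accuracy


def grid_search(
    dataset: LabeledDataset, config: SVMConfig | None = None, seed: int = 0
) -> GridSearchResult:
    """Exhaustive (C, γ) search scored by stratified inner-fold CV accuracy.

    Ties resolve toward smaller C, then smaller γ. The full accuracy table
    is returned for inspection.
    """
    config = config or SVMConfig()
    _validate_dataset(dataset)
    folds = min(config.inner_folds, dataset.n_pos, dataset.n_neg)
    if folds < 2:
        raise ValueError("each class needs >= 2 samples for inner CV")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(dataset.matrix, dataset.labels))
    rows = []
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            correct = 0
            for train_idx, test_idx in splits:
                est = SVC(C=C, gamma=gamma, kernel="rbf")
                est.fit(dataset.matrix[train_idx], dataset.labels[train_idx])
                pred = est.predict(dataset.matrix[test_idx])
                correct += int(np.sum(pred == dataset.labels[test_idx]))
            rows.append((C, gamma, correct / dataset.labels.shape[0]))
    table = pd.DataFrame(rows, columns=["C", "gamma", "accuracy"])
    # arg-max accuracy; ties toward smaller C then smaller gamma (input
    # ordering is increasing, so the first maximal row wins)
    best = table.loc[table["accuracy"].idxmax()]
    return GridSearchResult(
        C=float(best["C"]),
        gamma=float(best["gamma"]),
        accuracy=float(best["accuracy"]),
        table=table,
    )


@dataclass(frozen=True)
class Prediction:
    record_id: str
    label: str  # ncDNA or cDNA
    score: float


def _decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=np.float64)
    # probability-based models: signed margin around 1/2 for the +1 class
    proba = estimator.predict_proba(X)
    pos_col = int(np.where(estimator.classes_ == 1)[0][0])
    return np.asarray(proba[:, pos_col] - 0.5, dtype=np.float64)


def predict(
    model: ModelArtifact,
    vectors: TypingSequence[FeatureVector] | np.ndarray,
    record_ids: TypingSequence[str] | None = None,
) -> list[Prediction]:
    """Label probe vectors; score > 0 → ncDNA, score ≤ 0 → cDNA.

    The probe dimension must match the model's recorded feature space.
    """
    if isinstance(vectors, np.ndarray):
        X = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    else:
        X = np.vstack([np.asarray(v.values, dtype=np.float64) for v in vectors])
    expected = len(model.feature_names)
    if X.shape[1] != expected:
        raise ValueError(
            f"probe dimension {X.shape[1]} does not match model encoding "
            f"k={model.k!r} (expected {expected} features)"
        )
    if record_ids is None:
        record_ids = [f"record{i + 1}" for i in range(X.shape[0])]
    scores = _decision_scores(model.estimator, X)
    return [
        Prediction(rid, POSITIVE_LABEL if s > 0 else NEGATIVE_LABEL, float(s))
        for rid, s in zip(record_ids, scores)
    ]


def baseline_classifiers(
    dataset: LabeledDataset, spec: str, seed: int = 0
) -> ModelArtifact:
    """Fit one of the comparison classifiers with documented defaults.

    knn — 5 nearest neighbours, Euclidean; naive-bayes — Gaussian;
    random-forest — 100 trees; decision-tree — single CART tree.
    """
    _validate_dataset(dataset)
    est = build_estimator(spec, None, seed)
    est.fit(dataset.matrix, dataset.labels)
    return ModelArtifact(
        estimator=est,
        spec=spec,
        k=dataset.k,
        feature_names=list(dataset.feature_names),
        config=None,
        n_pos=dataset.n_pos,
        n_neg=dataset.n_neg,
        seed=seed,
        trained_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def build_estimator(spec: str, config: SVMConfig | None = None, seed: int = 0):
    """Fresh unfitted scikit-learn estimator for a classifier spec name."""
    if spec == "svm":
        config = config or SVMConfig()
        return SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if spec == "naive-bayes":
        return GaussianNB()
    if spec == "random-forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if spec == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier spec {spec!r}; choose from {CLASSIFIER_SPECS}")


# ---------------------------------------------------------------------------
# Persistence: self-describing joblib container
# ---------------------------------------------------------------------------


def save_model(model: ModelArtifact, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "python": platform.python_version(),
        "spec": model.spec,
        "k": model.k,
        "feature_names": model.feature_names,
        "config": model.config,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "seed": model.seed,
        "retained_features": model.retained_features,
        "trained_at": model.trained_at,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path) -> ModelArtifact:
    path = Path(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib file
        raise ValueError(f"cannot load model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an ncdna model container")
    if payload["format_version"] != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    return ModelArtifact(
        estimator=payload["estimator"],
        spec=payload["spec"],
        k=payload["k"],
        feature_names=list(payload["feature_names"]),
        config=payload["config"],
        n_pos=payload["n_pos"],
        n_neg=payload["n_neg"],
        seed=payload.get("seed"),
        retained_features=payload.get("retained_features"),
        trained_at=payload.get("trained_at", ""),
    )
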