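"""F-score feature ranking, tetramer heat-map grids, incremental selection.

For feature i with per-class sample means x̄ᵢ⁺ (positive), x̄ᵢ⁻ (negative)
and overall mean x̄ᵢ:

    F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻]

where s²ᵢ± are the within-class sample variances (n−1 denominators). Larger
F means better single-feature discrimination between the classes. A feature
that is constant within both classes has a zero denominator and is assigned
score 0 (it carries no usable signal). The score is symmetric in the two
classes and invariant under affine rescaling of a feature column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .kmer_features import LabeledDataset, enumerate_kmers

logger = logging.getLogger("ncdna")


@dataclass(frozen=True)
class FScoreRecord:
    """One feature with its F-score and 1-based rank (1 = highest score)."""

    feature_name: str
    score: float
    rank: int


def f_scores(dataset: LabeledDataset) -> np.ndarray:
    """Vector of F-scores for every column of the dataset.

    Requires at least two samples per class (sample variances use n−1).
    Zero-denominator columns score 0, with a warning.
    """
    if dataset.n_pos < 2 or dataset.n_neg < 2:
        raise ValueError(
            "F-score needs >= 2 samples per class "
            f"(got n_pos={dataset.n_pos}, n_neg={dataset.n_neg})"
        )
    X = dataset.matrix
    pos = X[dataset.labels == 1]
    neg = X[dataset.labels == -1]
    mean_all = X.mean(axis=0)
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    numer = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    zero = denom <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} feature(s) constant within both classes; "
            "F-score set to 0",
            stacklevel=2,
        )
    scores = np.zeros_like(numer)
    np.divide(numer, denom, out=scores, where=~zero)
    return scores


def f_score(dataset: LabeledDataset, feature_index: int) -> float:
    """F-score of one column (see :func:`f_scores`)."""
    if not 0 <= feature_index < dataset.n_features:
        raise IndexError(f"feature_index {feature_index} out of range")
    return float(f_scores(dataset)[feature_index])


def rank_features(dataset: LabeledDataset) -> list[FScoreRecord]:
    """All columns scored and sorted descending; ties broken lexicographically
    by feature name, so the ranking is deterministic."""
    scores = f_scores(dataset)
    order = sorted(
        range(len(scores)), key=lambda j: (-scores[j], dataset.feature_names[j])
    )
    return [
        FScoreRecord(dataset.feature_names[j], float(scores[j]), rank)
        for rank, j in enumerate(order, start=1)
    ]


def top_features(records: TypingSequence[FScoreRecord], n: int) -> list[str]:
    """Names of the first ``n`` features by rank."""
    if not 1 <= n <= len(records):
        raise ValueError(f"n must be in 1..{len(records)}, got {n}")
    ordered = sorted(records, key=lambda r: r.rank)
    return [r.feature_name for r in ordered[:n]]


# ---------------------------------------------------------------------------
# 16x16 tetramer heat-map grid
# ---------------------------------------------------------------------------


def default_heatmap_layout() -> pd.DataFrame:
    """Default 16×16 tetramer arrangement: rows indexed by the first two
    bases, columns by the last two, both lexicographic."""
    dimers = enumerate_kmers(2)
    grid = [[row + col for col in dimers] for row in dimers]
    return pd.DataFrame(grid, index=dimers, columns=dimers)


def load_heatmap_layout(path: str | Path) -> pd.DataFrame:
    """Load an alternative 16×16 label arrangement from a delimited file.

    The file holds 16 rows of 16 tab- or comma-separated tetramer labels
    (an optional first header row / index column of dimer labels is
    accepted). Together the 256 cells must be a permutation of all tetramers.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    values = df.to_numpy()
    # strip an optional header row / index column of dimer labels
    if values.shape == (17, 17):
        values = values[1:, 1:]
    if values.shape != (16, 16):
        raise ValueError(f"layout must be 16x16, got {values.shape}")
    dimers = enumerate_kmers(2)
    return pd.DataFrame(values, index=dimers, columns=dimers)


def heatmap_matrix(
    records: TypingSequence[FScoreRecord],
    layout: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Place the 256 tetramer F-scores on a 16×16 grid.

    ``records`` must contain exactly one score per tetramer. The default
    layout is lexicographic (first two bases → row, last two → column);
    any 16×16 label frame covering each tetramer once may be supplied.
    """
    expected = set(enumerate_kmers(4))
    by_name = {r.feature_name: r.score for r in records}
    if len(records) != 256 or set(by_name) != expected:
        missing = sorted(expected - set(by_name))[:5]
        extra = sorted(set(by_name) - expected)[:5]
        raise ValueError(
            "need exactly one record per tetramer; "
            f"missing={missing}... extra={extra}..."
        )
    if layout is None:
        layout = default_heatmap_layout()
    labels = layout.to_numpy()
    flat = [str(x) for x in labels.ravel()]
    if sorted(flat) != sorted(expected):
        raise ValueError("layout labels are not a permutation of the 256 tetramers")
    scores = np.array([[by_name[str(lab)] for lab in row] for row in labels])
    return pd.DataFrame(scores, index=layout.index, columns=layout.columns)


# ---------------------------------------------------------------------------
# Incremental feature selection along the ranked list
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IFSPoint:
    n_features: int
    metrics: "object"  # evaluation.Metrics; kept loose to avoid a cycle


@dataclass(frozen=True)
class IFSResult:
    curve: list[IFSPoint]
    best_n: int

    @property
    def best_metrics(self):
        for point in self.curve:
            if point.n_features == self.best_n:
                return point.metrics
        raise LookupError("best_n not on curve")


def default_ifs_step(n_features: int) -> int:
    """Step 1 for small feature spaces (m ≤ 64), else 8."""
    return 1 if n_features <= 64 else 8


def incremental_feature_selection(
    dataset: LabeledDataset,
    ranked: TypingSequence[FScoreRecord],
    evaluator: Callable[[LabeledDataset], "object"],
    step: int | None = None,
) -> IFSResult:
    """Evaluate nested top-n subsets (n = step, 2·step, ..., m) of the ranked
    feature list and report the accuracy-maximizing subset size.

    ``evaluator`` maps a column-subset dataset to a metrics object exposing
    ``acc`` (e.g. a :func:`ncdna.evaluation.cross_validate` closure). The
    final curve point always uses all m features. Ties in accuracy resolve
    toward the smaller subset.
    """
    m = dataset.n_features
    if step is None:
        step = default_ifs_step(m)
    if step < 1:
        raise ValueError("step must be >= 1")
    names = top_features(ranked, m)
    sizes = list(range(step, m + 1, step))
    if not sizes or sizes[-1] != m:
        sizes.append(m)
    curve: list[IFSPoint] = []
    for n in sizes:
        subset = dataset.subset_columns(names[:n])
        curve.append(IFSPoint(n, evaluator(subset)))
    best = max(curve, key=lambda p: (p.metrics.acc, -p.n_features))
    return IFSResult(curve=curve, best_n=best.n_features)


def ranking_to_frame(records: TypingSequence[FScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rank, r.feature_name, r.score) for r in sorted(records, key=lambda r: r.rank)],
        columns=["rank", "kmer", "f_score"],
    )


def write_ranking(records: TypingSequence[FScoreRecord], path: str | Path) -> Path:
    """Export the ranked score table (rank, k-mer, score; tab-delimited)."""
    path = Path(path)
    ranking_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def write_heatmap_grid(grid: pd.DataFrame, path: str | Path) -> Path:
    """Export the 16×16 score grid with dimer row/column labels."""
    path = Path(path)
    grid.to_csv(path, sep="\t", float_format="%.12g")
    return path
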