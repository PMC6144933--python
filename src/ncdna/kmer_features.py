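"""k-mer nucleotide composition encoding (k = 1..6) and labeled datasets.

A sequence P = R1 R2 ... RL is encoded as the vector of sliding-window
frequencies f_i = n_i / (L - k + 1) over the 4^k k-mers in lexicographic
order (A < C < G < T). Windows containing an ambiguous base are skipped and
the denominator becomes the number of valid windows, which preserves the
sum-to-one property; for pure-ACGT input this coincides with L - k + 1.

The single-k encodings are conventionally named by k: mono- (MNC), di- (DNC),
tri- (TNC), tetra- (TrNC), penta- (PNC) and hexanucleotide composition (HNC).
``COMBINED`` concatenates all six blocks into one 5460-dimensional vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .sequence_io import DNA_ALPHABET, Sequence

#: Sentinel for the concatenated k=1..6 encoding ("All Features").
COMBINED = "combined"

KS = (1, 2, 3, 4, 5, 6)

#: Canonical encoder names, keyed by k.
ENCODER_NAMES = {1: "MNC", 2: "DNC", 3: "TNC", 4: "TrNC", 5: "PNC", 6: "HNC"}

POSITIVE_LABEL = "ncDNA"
NEGATIVE_LABEL = "cDNA"

_BASES = "ACGT"


class EncodingError(ValueError):
    """A sequence cannot be encoded (too short, or no valid window)."""


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k k-mers over {A,C,G,T} in lexicographic order (A<C<G<T)."""
    if not isinstance(k, int) or not 1 <= k <= 6:
        raise ValueError(f"k must be an integer in 1..6, got {k!r}")
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def _kmer_index(kmer: str) -> int:
    # base-4 interpretation of the k-mer; assumes pure ACGT
    idx = 0
    for base in kmer:
        idx = idx * 4 + "ACGT".index(base)
    return idx


@dataclass(frozen=True)
class FeatureVector:
    """Normalized k-mer frequencies of one sequence.

    ``k`` is 1..6 or :data:`COMBINED`; ``valid_windows`` counts the sliding
    windows actually used (per k for combined, summed).
    """

    k: int | str
    values: np.ndarray
    valid_windows: int

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def kmer_frequencies(record: Sequence, k: int) -> FeatureVector:
    """Sliding-window k-mer frequency vector of one record.

    Raises :class:`EncodingError` if L < k or no window is free of ambiguous
    bases.
    """
    if not 1 <= int(k) <= 6:
        raise ValueError(f"k must be in 1..6, got {k!r}")
    seq = record.residues.upper()
    L = len(seq)
    if L < k:
        raise EncodingError(
            f"record {record.id!r} has length {L} < k={k}; cannot encode"
        )
    counts = np.zeros(4 ** k, dtype=np.float64)
    valid = 0
    # positions of ambiguous residues allow O(L) window validity tracking
    is_acgt = [c in DNA_ALPHABET for c in seq]
    bad_in_window = sum(1 for flag in is_acgt[:k] if not flag)
    for start in range(L - k + 1):
        if start > 0:
            bad_in_window += (not is_acgt[start + k - 1]) - (not is_acgt[start - 1])
        if bad_in_window == 0:
            counts[_kmer_index(seq[start : start + k])] += 1
            valid += 1
    if valid == 0:
        raise EncodingError(
            f"record {record.id!r} has no window of length {k} free of ambiguous bases"
        )
    return FeatureVector(k=k, values=counts / valid, valid_windows=valid)


def combined_features(record: Sequence) -> FeatureVector:
    """Concatenation of the six single-k vectors, k = 1..6 (dimension 5460)."""
    if record.length < 6:
        raise EncodingError(
            f"record {record.id!r} has length {record.length} < 6; "
            "combined encoding needs all of k=1..6"
        )
    parts = [kmer_frequencies(record, k) for k in KS]
    return FeatureVector(
        k=COMBINED,
        values=np.concatenate([p.values for p in parts]),
        valid_windows=sum(p.valid_windows for p in parts),
    )


def feature_names(k: int | str) -> list[str]:
    """Column names for a single-k or combined encoding."""
    if k == COMBINED:
        return [name for kk in KS for name in enumerate_kmers(kk)]
    return enumerate_kmers(int(k))


@dataclass
class LabeledDataset:
    """Feature matrix with binary class labels.

    ``labels`` holds +1 for the positive class (ncDNA) and -1 for the
    negative class (cDNA). Column order always follows
    :func:`enumerate_kmers` — the ranking and heat-map layers rely on it.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    k: int | str
    record_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix rows and labels disagree")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix columns and feature_names disagree")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 (ncDNA) or -1 (cDNA)")

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_columns(self, names: TypingSequence[str]) -> "LabeledDataset":
        """Restrict to the given feature columns, in the given order."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        cols = [index[n] for n in names]
        return LabeledDataset(
            matrix=self.matrix[:, cols],
            labels=self.labels.copy(),
            feature_names=list(names),
            k=self.k,
            record_ids=list(self.record_ids),
        )


def encode_dataset(
    pos: Iterable[Sequence],
    neg: Iterable[Sequence],
    k: int | str,
    on_error: Literal["raise", "skip"] = "raise",
) -> LabeledDataset:
    """Encode positive (ncDNA) and negative (cDNA) records into one dataset.

    Rows are positives first, in input order. With ``on_error="skip"``,
    un-encodable records are dropped with a warning instead of aborting;
    the default aggregates all offending ids into a single error.
    """
    pos = list(pos)
    neg = list(neg)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")

    def _encode(rec: Sequence) -> np.ndarray:
        if k == COMBINED:
            return combined_features(rec).values
        return kmer_frequencies(rec, int(k)).values

    rows: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    failures: list[str] = []
    for label, group in ((1, pos), (-1, neg)):
        for rec in group:
            try:
                rows.append(_encode(rec))
            except EncodingError as exc:
                if on_error == "skip":
                    import logging

                    logging.getLogger("ncdna").warning("skipping record: %s", exc)
                    continue
                failures.append(rec.id)
                continue
            labels.append(label)
            ids.append(rec.id)
    if failures:
        raise EncodingError(
            f"{len(failures)} record(s) could not be encoded at k={k}: "
            + ", ".join(repr(f) for f in failures)
        )
    if not rows:
        raise EncodingError("no record could be encoded")
    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.array(labels),
        feature_names=feature_names(k),
        k=k,
        record_ids=ids,
    )


# ---------------------------------------------------------------------------
# Delimited feature-table round trip (header = feature names + label column)
# ---------------------------------------------------------------------------

_LABEL_COLUMN = "label"
_ID_COLUMN = "record_id"


def dataset_to_frame(dataset: LabeledDataset) -> pd.DataFrame:
    df = pd.DataFrame(dataset.matrix, columns=dataset.feature_names)
    df.insert(0, _ID_COLUMN, dataset.record_ids)
    df[_LABEL_COLUMN] = np.where(dataset.labels == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
    return df


def write_feature_table(dataset: LabeledDataset, path: str | Path) -> Path:
    """Export as a tab-delimited table: record_id, one column per k-mer, label."""
    path = Path(path)
    dataset_to_frame(dataset).to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> LabeledDataset:
    """Re-ingest a table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    if _LABEL_COLUMN not in df.columns:
        raise ValueError(f"feature table {path} lacks a {_LABEL_COLUMN!r} column")
    names = [c for c in df.columns if c not in (_LABEL_COLUMN, _ID_COLUMN)]
    labels = np.where(df[_LABEL_COLUMN].to_numpy() == POSITIVE_LABEL, 1, -1)
    ids = (
        df[_ID_COLUMN].astype(str).tolist()
        if _ID_COLUMN in df.columns
        else [f"row{i}" for i in range(len(df))]
    )
    k = _infer_k(names)
    return LabeledDataset(
        matrix=df[names].to_numpy(dtype=np.float64),
        labels=labels,
        feature_names=names,
        k=k,
        record_ids=ids,
    )


def _infer_k(names: TypingSequence[str]) -> int | str:
    lengths = {len(n) for n in names}
    if lengths == {len(names[0])} and len(names) == 4 ** len(names[0]):
        return len(names[0])
    if list(names) == feature_names(COMBINED):
        return COMBINED
    # subset tables (e.g. after feature selection) keep the k of their parent
    if len(lengths) == 1:
        return len(names[0])
    return COMBINED
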