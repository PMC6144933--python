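"""Seeded synthetic benchmarks: two sequence classes with planted k-mer bias.

Sequences are emitted by a Markov chain whose order is tied to the longest
planted k-mer (order k−1), so a specific k-mer can be enriched exactly: at
each step the next-base weights start from the background composition, and
any base that would complete a planted k-mer given the current context has
its weight multiplied by that k-mer's enrichment factor before
renormalization. With all factors at 1 the two classes are statistically
indistinguishable — the null case the evaluation tests rely on.

Lengths are uniform over a configurable range, by default 100..800 nt, the
regime where most annotated non-coding elements fall. Everything is fully
determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import Sequence, write_fasta

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class benchmark.

    ``bias_kmers`` maps planted k-mers to enrichment factors (> 0) applied
    to the positive class only. ``background`` is the stationary base
    composition (A, C, G, T), default uniform.
    """

    n_pos: int = 300
    n_neg: int = 300
    length_range: tuple[int, int] = (100, 800)
    bias_kmers: tuple[tuple[str, float], ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        for kmer, factor in self.bias_kmers:
            if not kmer or set(kmer) - set(_BASES):
                raise ValueError(f"bias k-mer {kmer!r} must be non-empty over ACGT")
            if factor <= 0:
                raise ValueError(f"enrichment factor for {kmer!r} must be > 0")
            if len(kmer) > lo:
                raise ValueError(
                    f"minimum length {lo} is shorter than bias k-mer {kmer!r}"
                )
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @property
    def order(self) -> int:
        """Markov order: longest planted k-mer minus one (0 without bias)."""
        return max((len(k) for k, _ in self.bias_kmers), default=1) - 1


def _transition_weights(spec: SyntheticSpec, biased: bool) -> dict[str, np.ndarray]:
    """Per-context next-base probability rows (contexts shorter than the
    order cover the sequence start)."""
    weights: dict[str, np.ndarray] = {}
    bg = np.asarray(spec.background, dtype=float)

    def row(context: str) -> np.ndarray:
        w = bg.copy()
        if biased:
            for kmer, factor in spec.bias_kmers:
                prefix, last = kmer[:-1], kmer[-1]
                if len(prefix) <= len(context) and context.endswith(prefix):
                    w[_BASE_INDEX[last]] *= factor
        return w / w.sum()

    contexts = [""]
    frontier = [""]
    for _ in range(spec.order):
        frontier = [c + b for c in frontier for b in _BASES]
        contexts += frontier
    for c in contexts:
        weights[c] = np.cumsum(row(c))
    return weights


def _sample_sequence(
    length: int, cum_weights: dict[str, np.ndarray], order: int,
    rng: np.random.Generator,
) -> str:
    out: list[str] = []
    uniforms = rng.random(length)
    for u in uniforms:
        context = "".join(out[-order:]) if order > 0 else ""
        cw = cum_weights[context]
        out.append(_BASES[int(np.searchsorted(cw, u, side="right"))])
    return "".join(out)


def generate_class(
    n: int, spec: SyntheticSpec, biased: bool, id_prefix: str | None = None
) -> list[Sequence]:
    """Sample ``n`` records from the background chain, with the planted
    enrichments applied when ``biased``. Fully determined by ``spec.seed``
    (the two classes use independent seeded streams)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if id_prefix is None:
        id_prefix = "nc" if biased else "cd"
    rng = np.random.default_rng([spec.seed, int(bool(biased))])
    weights = _transition_weights(spec, biased)
    lo, hi = spec.length_range
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            Sequence(
                id=f"{id_prefix}{i + 1}",
                residues=_sample_sequence(length, weights, spec.order, rng),
            )
        )
    return records


@dataclass(frozen=True)
class Benchmark:
    """A generated two-class benchmark with its file locations."""

    positive: list[Sequence] = field(repr=False)
    negative: list[Sequence] = field(repr=False)
    pos_path: Path | None = None
    neg_path: Path | None = None
    manifest_path: Path | None = None
    spec: SyntheticSpec = SyntheticSpec()


def generate_benchmark(spec: SyntheticSpec, out_dir: str | Path | None = None) -> Benchmark:
    """Generate the positive (biased) and negative (background) classes.

    With ``out_dir`` given, writes ``positive.fasta``, ``negative.fasta``
    and a ``manifest.txt`` recording the spec, seed and planted k-mers so
    downstream recovery checks know the ground truth.
    """
    positive = generate_class(spec.n_pos, spec, biased=True)
    negative = generate_class(spec.n_neg, spec, biased=False)
    pos_path = neg_path = manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pos_path = write_fasta(positive, out_dir / "positive.fasta")
        neg_path = write_fasta(negative, out_dir / "negative.fasta")
        manifest_path = write_manifest(spec, out_dir / "manifest.txt")
    return Benchmark(positive, negative, pos_path, neg_path, manifest_path, spec)


# ---------------------------------------------------------------------------
# Manifest: small key-value text file with the planted truth
# ---------------------------------------------------------------------------


def write_manifest(spec: SyntheticSpec, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"n_pos={spec.n_pos}",
        f"n_neg={spec.n_neg}",
        f"length_min={spec.length_range[0]}",
        f"length_max={spec.length_range[1]}",
        "background=" + ",".join(f"{p:.12g}" for p in spec.background),
        f"seed={spec.seed}",
    ]
    lines += [f"bias\t{kmer}\t{factor:.12g}" for kmer, factor in spec.bias_kmers]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path: str | Path) -> SyntheticSpec:
    kv: dict[str, str] = {}
    bias: list[tuple[str, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("bias\t"):
            _, kmer, factor = line.split("\t")
            bias.append((kmer, float(factor)))
        else:
            key, value = line.split("=", 1)
            kv[key] = value
    return SyntheticSpec(
        n_pos=int(kv["n_pos"]),
        n_neg=int(kv["n_neg"]),
        length_range=(int(kv["length_min"]), int(kv["length_max"])),
        bias_kmers=tuple(bias),
        background=tuple(float(x) for x in kv["background"].split(",")),
        seed=int(kv["seed"]),
    )
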