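import numpy as np
import pytest

from ncdna import (
    LabeledDataset,
    Sequence,
    SyntheticSpec,
    encode_dataset,
    generate_benchmark,
)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def toy_separable() -> LabeledDataset:
    """Linearly separated 2-feature set: positives near (1, 0), negatives
    near (0, 1)."""
    gen = np.random.default_rng(7)
    pos = np.column_stack([1 + 0.05 * gen.standard_normal(20),
                           0.05 * gen.standard_normal(20)])
    neg = np.column_stack([0.05 * gen.standard_normal(20),
                           1 + 0.05 * gen.standard_normal(20)])
    return LabeledDataset(
        matrix=np.vstack([pos, neg]),
        labels=np.r_[np.ones(20, dtype=int), -np.ones(20, dtype=int)],
        feature_names=["f1", "f2"],
        k=1,
        record_ids=[f"r{i}" for i in range(40)],
    )


@pytest.fixture(scope="session")
def planted_benchmark():
    """Small planted-bias benchmark shared by ranking/classifier tests."""
    spec = SyntheticSpec(
        n_pos=120, n_neg=120, length_range=(100, 300),
        bias_kmers=(("TATA", 4.0), ("TTTT", 4.0), ("ATAT", 4.0)), seed=11,
    )
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def planted_dataset(planted_benchmark) -> LabeledDataset:
    return encode_dataset(planted_benchmark.positive, planted_benchmark.negative, 4)


@pytest.fixture()
def small_records(rng) -> list[Sequence]:
    return [
        Sequence(f"s{i}", random_dna(np.random.default_rng(100 + i),
                                     int(np.random.default_rng(200 + i).integers(10, 60))))
        for i in range(6)
    ]
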