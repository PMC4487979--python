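import numpy as np
import pytest

from kmertax import (
    KmerDictionary,
    SequenceRecord,
    CommunitySpec,
    generate_community,
)


@pytest.fixture(scope="session")
def dict2() -> KmerDictionary:
    return KmerDictionary(2)


@pytest.fixture(scope="session")
def toy_two_genus() -> list[SequenceRecord]:
    """Two one-sequence genera with hand-checkable K=2 statistics."""
    return [
        SequenceRecord("s1", "AAA", genus="g1"),
        SequenceRecord("s2", "CCC", genus="g2"),
    ]


@pytest.fixture(scope="session")
def disjoint_alphabet_corpus() -> list[SequenceRecord]:
    """Two genera with disjoint alphabets: A/C words vs G/T words.

    Perfectly separable at K=2 — every classifier should reach zero
    training-set error.
    """
    rng = np.random.default_rng(42)
    records = []
    for i in range(8):
        seq = "".join("AC"[b] for b in rng.integers(0, 2, 120))
        records.append(SequenceRecord(f"ac{i}", seq, genus="AcGenus"))
    for i in range(8):
        seq = "".join("GT"[b] for b in rng.integers(0, 2, 120))
        records.append(SequenceRecord(f"gt{i}", seq, genus="GtGenus"))
    return records


@pytest.fixture(scope="session")
def easy_community() -> list[SequenceRecord]:
    """Well-separated synthetic corpus for fast end-to-end CV checks."""
    spec = CommunitySpec(
        genus_sizes=[5] * 10,
        d_between=0.25,
        d_within=0.01,
        length=600,
        length_jitter=0,
        seed=3,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def recovery_community() -> list[SequenceRecord]:
    """The parameter-recovery corpus: 30 genera, sizes 5-20, ~1500 bases.

    Includes two singleton genera appended so the singleton-exclusion
    bookkeeping is exercised under cross-validation.
    """
    rng = np.random.default_rng(11)
    sizes = list(rng.integers(5, 21, size=30)) + [1, 1]
    spec = CommunitySpec(
        genus_sizes=sizes,
        d_between=0.25,
        d_within=0.01,
        length=1500,
        length_jitter=100,
        seed=11,
    )
    return generate_community(spec)
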