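"""K-mer feature extraction for DNA/RNA sequences.

Every classifier in this package represents a sequence by its overlapping
words of length K over the alphabet A < C < G < T.  There are D = 4**K
possible words, ordered alphabetically, and a sequence becomes a length-D
vector in one of three modes:

``frequency``
    raw overlapping word counts,
``presence``
    0/1 indicator of each word occurring at least once,
``profile``
    frequencies divided by their sum (multinomial probabilities).

RNA input is handled by mapping U to T; case is folded.  Any window that
contains a symbol outside {A, C, G, T} after this normalization (IUPAC
ambiguity codes, gaps, etc.) is skipped rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger("kmertax")

ALPHABET = "ACGT"

#: byte -> base code lookup; -1 marks symbols that invalidate a window
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3  # 16S rRNA given as RNA
_CODE[ord("u")] = 3


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with an identifier and an optional genus label."""

    id: str
    residues: str
    genus: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")


@dataclass(frozen=True)
class KmerDictionary:
    """The D = 4**K words of length K in alphabetical order.

    Word j (0-based) is the base-4 expansion of j over A=0, C=1, G=2, T=3,
    so consecutive blocks of four indices share the same (K-1)-base pretext
    — the layout the Markov classifier relies on.
    """

    k: int

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or not 1 <= self.k <= 12:
            raise ValueError(f"word length K must be an integer in [1, 12], got {self.k!r}")

    @property
    def size(self) -> int:
        """Vocabulary size D = 4**K."""
        return 4 ** self.k

    def word(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise IndexError(f"word index {index} out of range for K={self.k}")
        letters = []
        for _ in range(self.k):
            letters.append(ALPHABET[index % 4])
            index //= 4
        return "".join(reversed(letters))

    def index(self, word: str) -> int:
        if len(word) != self.k:
            raise ValueError(f"word {word!r} does not have length K={self.k}")
        idx = 0
        for ch in word.upper().replace("U", "T"):
            code = ALPHABET.find(ch)
            if code < 0:
                raise ValueError(f"word {word!r} contains a non-ACGT symbol")
            idx = idx * 4 + code
        return idx

    def words(self) -> list[str]:
        """All D words in alphabetical order (intended for small K)."""
        return [self.word(j) for j in range(self.size)]


@dataclass(frozen=True)
class CountVector:
    """A length-D K-mer vector in one of the three representation modes."""

    values: np.ndarray
    mode: str  # "presence" | "frequency" | "profile"

    def __post_init__(self) -> None:
        if self.mode not in ("presence", "frequency", "profile"):
            raise ValueError(f"unknown CountVector mode {self.mode!r}")


def build_dictionary(k: int) -> KmerDictionary:
    """Return the alphabetically ordered K-mer vocabulary for word length ``k``."""
    return KmerDictionary(int(k))


def encode(residues: str) -> np.ndarray:
    """Map residues to base codes 0-3 (A, C, G, T); -1 for anything else."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def _window_indices(residues: str, k: int) -> np.ndarray:
    """Dictionary indices of all valid overlapping windows, in sequence order."""
    codes = encode(residues)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid].astype(np.int64) @ powers


def count_kmers(seq, dictionary: KmerDictionary) -> CountVector:
    """Count overlapping K-mer occurrences in a sequence.

    Accepts a :class:`SequenceRecord` or a plain string.  Windows containing
    non-ACGT symbols (after U->T and case folding) are skipped, so the total
    count is at most len(seq) - K + 1.  A sequence with no countable window
    yields an all-zero vector and a warning.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    idx = _window_indices(residues, dictionary.k)
    values = np.bincount(idx, minlength=dictionary.size).astype(np.int64)
    if idx.size == 0:
        name = seq.id if isinstance(seq, SequenceRecord) else "<anonymous>"
        logger.warning("sequence %s has no countable %d-mer window", name, dictionary.k)
    return CountVector(values=values, mode="frequency")


def count_matrix(seqs: Iterable, dictionary: KmerDictionary) -> np.ndarray:
    """Stack K-mer frequency vectors of many sequences into an (N x D) matrix."""
    rows = [count_kmers(s, dictionary).values for s in seqs]
    if not rows:
        return np.empty((0, dictionary.size), dtype=np.int64)
    return np.vstack(rows)


def to_presence(freq: CountVector) -> CountVector:
    """Collapse a frequency vector to the 0/1 presence indicator."""
    if freq.mode != "frequency":
        raise ValueError(f"to_presence expects mode='frequency', got {freq.mode!r}")
    return CountVector(values=(freq.values >= 1).astype(np.int64), mode="presence")


def to_profile(freq: CountVector) -> CountVector:
    """Normalize a frequency vector to a multinomial profile summing to 1."""
    if freq.mode != "frequency":
        raise ValueError(f"to_profile expects mode='frequency', got {freq.mode!r}")
    total = freq.values.sum()
    if total <= 0:
        raise ValueError("cannot form a profile from an all-zero frequency vector")
    return CountVector(values=freq.values / total, mode="profile")


def presence_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise presence indicators of a frequency count matrix."""
    return (counts >= 1).astype(np.float64)


def profile_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a frequency count matrix to multinomial profiles.

    Rows with zero total (degenerate sequences) are left as all-zero rows;
    callers decide whether to skip or reject them.
    """
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return counts / safe
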