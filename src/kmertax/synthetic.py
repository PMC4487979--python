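"""Synthetic genus-labelled 16S-like communities.

Real 16S reference corpora have two structural features the classifiers are
sensitive to: a strongly right-skewed genus-size distribution (singleton
genera are the most common) and within-genus sequence divergence far smaller
than between-genus divergence.  This module generates corpora with exactly
those features so the whole pipeline is testable without external downloads.

The model is a star phylogeny with substitution-only mutation: one random
root sequence; each genus gets an ancestor by mutating the root at per-site
rate ``d_between``; each sequence mutates its genus ancestor at per-site rate
``d_within``.  Substitutions pick uniformly among the three alternative
bases.  No indels, no conserved/hypervariable region structure, no
sequencing-error model — adequate for controlling separability, not for
emulating real 16S evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kmers import ALPHABET, SequenceRecord

_BASES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic genus-labelled community.

    ``genus_sizes`` fixes sizes explicitly; otherwise ``n_genera`` sizes are
    drawn from a discrete power law P(s) proportional to s**(-size_skew) on
    1..max_size, whose mode at s=1 reproduces the singleton-heavy skew of
    real reference sets.  Sequence lengths are uniform on
    length +- length_jitter (default ~1500 bases, the full 16S gene).
    """

    n_genera: int = 50
    genus_sizes: Optional[Sequence[int]] = None
    size_skew: float = 1.8
    max_size: int = 50
    length: int = 1500
    length_jitter: int = 100
    d_between: float = 0.25
    d_within: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_within < self.d_between <= 0.75:
            raise ValueError(
                f"need 0 <= d_within < d_between <= 0.75, got "
                f"d_within={self.d_within}, d_between={self.d_between}"
            )
        if self.genus_sizes is not None:
            if len(self.genus_sizes) == 0 or any(s < 1 for s in self.genus_sizes):
                raise ValueError("explicit genus sizes must be >= 1")
        elif self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.length - self.length_jitter < 1:
            raise ValueError("length_jitter leaves no room for a sequence")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """A uniform random ACGT sequence."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site takes one of the three alternative bases uniformly,
    so the original base is never retained at a mutated site.  Length is
    preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    # map bytes to 0..3 via ACGT index
    lookup = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        lookup[ord(b)] = i
    base_idx = lookup[codes]
    hit = rng.random(codes.size) < rate
    offsets = rng.integers(1, 4, size=codes.size)  # never 0 -> base always changes
    new_idx = np.where(hit, (base_idx + offsets) % 4, base_idx)
    return _BASES[new_idx].tobytes().decode("ascii")


def sample_genus_sizes(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    """Draw genus sizes from the truncated power law of the spec."""
    sizes = np.arange(1, spec.max_size + 1, dtype=np.float64)
    weights = sizes ** (-spec.size_skew)
    weights /= weights.sum()
    return rng.choice(np.arange(1, spec.max_size + 1), size=spec.n_genera, p=weights)


def generate_community(spec: CommunitySpec) -> list[SequenceRecord]:
    """Generate a labelled corpus; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    if spec.genus_sizes is not None:
        sizes = np.asarray(spec.genus_sizes, dtype=np.int64)
    else:
        sizes = sample_genus_sizes(spec, rng)

    root = random_sequence(spec.length + spec.length_jitter, rng)
    records: list[SequenceRecord] = []
    width = len(str(len(sizes)))
    for g, size in enumerate(sizes):
        genus = f"Genus{g + 1:0{width}d}"
        ancestor = mutate_sequence(root, spec.d_between, rng)
        for s in range(size):
            seq = mutate_sequence(ancestor, spec.d_within, rng)
            if spec.length_jitter > 0:
                L = int(rng.integers(spec.length - spec.length_jitter,
                                     spec.length + spec.length_jitter + 1))
            else:
                L = spec.length
            records.append(
                SequenceRecord(id=f"{genus}_seq{s + 1}", residues=seq[:L], genus=genus)
            )
    return records
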