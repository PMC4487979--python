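"""The four direct K-mer classifiers and the shared assignment rule.

All four methods train a (G x D) matrix of log2 probabilities (or, for the
nearest-neighbour method, keep the training profiles themselves) and share
one decision rule: assign to the genus with the strictly largest score, or
return the sentinel ``"unclassified"`` when two or more genera tie.

Methods
-------
rdp
    Naive Bayes on word presence/absence.  Word background probabilities
    Pr(w_j) = (n_j + 0.5) / (N + 1) with n_j the number of training sequences
    containing w_j; genus-conditional probabilities
    q_gj = (m_gj + Pr(w_j)) / (M_g + 1) with m_gj the number of genus-g
    sequences containing w_j.  Score z = p + L a' with a the presence vector,
    L = log2 Q and p the log2 priors.
multinomial
    Naive Bayes on word frequencies.  Pseudo-counted genus frequencies
    F(w_j|g) = m_gj / M_g + 1/D (m_gj now a summed frequency) are
    row-normalized to multinomial probabilities; score z = p + L a' with a
    the raw frequency vector.
markov
    Order K-1 Markov chain.  From the same pseudo-counted F, the four
    extensions of each (K-1)-base pretext are normalized to transition
    probabilities; thanks to the alphabetical word order these occupy
    consecutive index quadruples {4h..4h+3}.  Score z = L a' (no prior term).
nn
    Nearest neighbour under Euclidean distance between multinomial profiles;
    the model is the training profile matrix itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kmers import (
    KmerDictionary,
    CountVector,
    count_kmers,
    count_matrix,
    presence_matrix,
    profile_matrix,
)

logger = logging.getLogger("kmertax")

UNCLASSIFIED = "unclassified"

#: relative tolerance for declaring two scores (or distances) tied
TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GenusAssignment:
    """The outcome of classifying one query sequence."""

    genus: str  # a genus name or UNCLASSIFIED
    scores: np.ndarray  # per-genus score vector z (higher is better)
    method: str = ""

    @property
    def classified(self) -> bool:
        return self.genus != UNCLASSIFIED


@dataclass(frozen=True)
class RdpModel:
    genera: list[str]
    k: int
    word_prob: np.ndarray  # Pr(w_j), length D
    log_q: np.ndarray  # L^rdp, (G x D) log2 conditional presence probabilities


@dataclass(frozen=True)
class MultinomialModel:
    genera: list[str]
    k: int
    log_q: np.ndarray  # L^mlt, (G x D); 2**row sums to 1


@dataclass(frozen=True)
class MarkovModel:
    genera: list[str]
    k: int
    log_q: np.ndarray  # L^mrk, (G x D) transitions in K-mer alphabetical order

    def pretext_index_set(self, last_base: int) -> np.ndarray:
        """Indices of K-mers ending in the given base (0=A..3=T)."""
        return np.arange(last_base, 4 ** self.k, 4)


@dataclass(frozen=True)
class NnModel:
    genera: list[str]  # distinct genus names, in first-seen training order
    k: int
    profiles: np.ndarray  # A^mlt, (N x D), each row sums to 1
    row_genus: np.ndarray = field(default=None)  # genus index per row, length N


def _check_labels(labels: Sequence[Optional[str]]) -> list[str]:
    if len(labels) == 0:
        raise ValueError("training set is empty")
    for i, g in enumerate(labels):
        if not g:
            raise ValueError(f"training record at position {i} has no genus label")
    return list(labels)


def _genus_table(labels: Sequence[str]) -> tuple[list[str], np.ndarray]:
    """Distinct genera in first-seen order plus the per-row genus index."""
    genera: list[str] = []
    index: dict[str, int] = {}
    row_genus = np.empty(len(labels), dtype=np.int64)
    for i, g in enumerate(labels):
        if g not in index:
            index[g] = len(genera)
            genera.append(g)
        row_genus[i] = index[g]
    return genera, row_genus


def _records_to_counts(training, dictionary: KmerDictionary) -> tuple[np.ndarray, list[str]]:
    labels = _check_labels([r.genus for r in training])
    return count_matrix(training, dictionary), labels


def compute_log_priors(genus_sizes: Sequence[int], mode: str = "flat") -> np.ndarray:
    """Log2 prior per genus.

    ``flat`` returns the all-zero vector: a shared constant never changes the
    argmax, so equal priors are represented by omitting the term.
    ``abundance`` returns log2(M_g / N), the training-set proportions.
    """
    sizes = np.asarray(genus_sizes, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("empty genus list")
    if np.any(sizes < 1):
        raise ValueError("every genus must have at least one training sequence")
    if mode == "flat":
        return np.zeros(sizes.size)
    if mode == "abundance":
        return np.log2(sizes / sizes.sum())
    raise ValueError(f"unknown prior mode {mode!r}")


def genus_sizes_from_labels(labels: Sequence[str], genera: Sequence[str]) -> np.ndarray:
    """Number of training sequences per genus, aligned with ``genera``."""
    counts = {g: 0 for g in genera}
    for g in labels:
        counts[g] += 1
    return np.array([counts[g] for g in genera], dtype=np.int64)


# ---------------------------------------------------------------------------
# training (from a precomputed frequency count matrix, or from records)
# ---------------------------------------------------------------------------


def _genus_sums(matrix: np.ndarray, row_genus: np.ndarray, n_genera: int) -> np.ndarray:
    """Sum rows of ``matrix`` by genus -> (G x D)."""
    out = np.zeros((n_genera, matrix.shape[1]), dtype=np.float64)
    np.add.at(out, row_genus, matrix)
    return out


def rdp_from_counts(counts: np.ndarray, labels: Sequence[str], k: int) -> RdpModel:
    labels = _check_labels(labels)
    genera, row_genus = _genus_table(labels)
    presence = presence_matrix(counts)
    n = presence.shape[0]
    n_j = presence.sum(axis=0)
    word_prob = (n_j + 0.5) / (n + 1)  # in (0, 1) by construction
    m = _genus_sums(presence, row_genus, len(genera))
    sizes = genus_sizes_from_labels(labels, genera).astype(np.float64)
    q = (m + word_prob[None, :]) / (sizes[:, None] + 1.0)
    return RdpModel(genera=genera, k=k, word_prob=word_prob, log_q=np.log2(q))


def multinomial_from_counts(counts: np.ndarray, labels: Sequence[str], k: int) -> MultinomialModel:
    labels = _check_labels(labels)
    genera, row_genus = _genus_table(labels)
    f = _pseudo_frequencies(counts, labels, genera, row_genus)
    q = f / f.sum(axis=1, keepdims=True)
    return MultinomialModel(genera=genera, k=k, log_q=np.log2(q))


def markov_from_counts(counts: np.ndarray, labels: Sequence[str], k: int) -> MarkovModel:
    if k < 2:
        raise ValueError("the Markov classifier needs K >= 2 (a non-empty pretext)")
    labels = _check_labels(labels)
    genera, row_genus = _genus_table(labels)
    f = _pseudo_frequencies(counts, labels, genera, row_genus)
    # alphabetical order puts the four extensions of each pretext in
    # consecutive columns; normalize each quadruple to sum to 1
    g_, d = f.shape
    blocks = f.reshape(g_, d // 4, 4)
    q = (blocks / blocks.sum(axis=2, keepdims=True)).reshape(g_, d)
    return MarkovModel(genera=genera, k=k, log_q=np.log2(q))


def _pseudo_frequencies(counts, labels, genera, row_genus) -> np.ndarray:
    """Pseudo-counted genus frequencies F(w_j|g) = m_gj / M_g + 1/D."""
    d = counts.shape[1]
    m = _genus_sums(np.asarray(counts, dtype=np.float64), row_genus, len(genera))
    sizes = genus_sizes_from_labels(labels, genera).astype(np.float64)
    return m / sizes[:, None] + 1.0 / d


def nn_from_counts(counts: np.ndarray, labels: Sequence[str], k: int) -> NnModel:
    labels = _check_labels(labels)
    totals = np.asarray(counts).sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        for i in np.flatnonzero(~keep):
            logger.warning(
                "skipping degenerate training sequence (no countable K-mer) at row %d", i
            )
    kept_labels = [g for g, ok in zip(labels, keep) if ok]
    if not kept_labels:
        raise ValueError("no training sequence has a countable K-mer")
    genera, row_genus = _genus_table(kept_labels)
    return NnModel(
        genera=genera,
        k=k,
        profiles=profile_matrix(np.asarray(counts)[keep]),
        row_genus=row_genus,
    )


def train_rdp(training, dictionary: KmerDictionary) -> RdpModel:
    """Train the presence/absence naive Bayes model on labelled records."""
    counts, labels = _records_to_counts(training, dictionary)
    return rdp_from_counts(counts, labels, dictionary.k)


def train_multinomial(training, dictionary: KmerDictionary) -> MultinomialModel:
    """Train the word-frequency naive Bayes model on labelled records."""
    counts, labels = _records_to_counts(training, dictionary)
    return multinomial_from_counts(counts, labels, dictionary.k)


def train_markov(training, dictionary: KmerDictionary) -> MarkovModel:
    """Train the order K-1 Markov chain model on labelled records."""
    counts, labels = _records_to_counts(training, dictionary)
    return markov_from_counts(counts, labels, dictionary.k)


def train_nn(training, dictionary: KmerDictionary) -> NnModel:
    """Store the multinomial profile of every labelled training record."""
    counts, labels = _records_to_counts(training, dictionary)
    return nn_from_counts(counts, labels, dictionary.k)


# ---------------------------------------------------------------------------
# scoring and assignment
# ---------------------------------------------------------------------------


def _check_dim(model_log_q: np.ndarray, values: np.ndarray) -> None:
    if values.shape[-1] != model_log_q.shape[1]:
        raise ValueError(
            f"query dimension {values.shape[-1]} does not match model D={model_log_q.shape[1]}"
        )


def score_rdp(model: RdpModel, query: CountVector, priors: Optional[np.ndarray] = None) -> np.ndarray:
    """Score vector z = p + L^rdp a' for a presence query vector."""
    if query.mode != "presence":
        raise ValueError(f"score_rdp expects mode='presence', got {query.mode!r}")
    _check_dim(model.log_q, query.values)
    z = model.log_q @ query.values.astype(np.float64)
    return z if priors is None else z + priors


def score_multinomial(
    model: MultinomialModel, query: CountVector, priors: Optional[np.ndarray] = None
) -> np.ndarray:
    """Score vector z = p + L^mlt a' for a frequency query vector."""
    if query.mode != "frequency":
        raise ValueError(f"score_multinomial expects mode='frequency', got {query.mode!r}")
    _check_dim(model.log_q, query.values)
    z = model.log_q @ query.values.astype(np.float64)
    return z if priors is None else z + priors


def score_markov(model: MarkovModel, query: CountVector) -> np.ndarray:
    """Score vector z = L^mrk a' for a frequency query vector (no prior term)."""
    if query.mode != "frequency":
        raise ValueError(f"score_markov expects mode='frequency', got {query.mode!r}")
    _check_dim(model.log_q, query.values)
    return model.log_q @ query.values.astype(np.float64)


def assign_from_scores(z: np.ndarray, genera: Sequence[str], method: str = "") -> GenusAssignment:
    """Assign to the genus with the unique maximum score.

    Two scores tie when |z_max - z| <= 1e-12 * max(1, |z_max|); a tied
    maximum yields the ``unclassified`` sentinel.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("score vector contains non-finite values")
    z_max = z.max()
    top = np.flatnonzero(z_max - z <= TIE_RTOL * max(1.0, abs(z_max)))
    genus = genera[top[0]] if top.size == 1 else UNCLASSIFIED
    return GenusAssignment(genus=genus, scores=z, method=method)


def nearest_genus(
    distances: np.ndarray,
    row_genus: np.ndarray,
    genera: Sequence[str],
    method: str = "",
) -> GenusAssignment:
    """Shared nearest-neighbour decision rule.

    Takes per-training-row distances; ties at the minimum (tolerance 1e-12,
    relative) spanning more than one genus yield ``unclassified``.  The
    reported score vector holds, per genus, minus the distance to its nearest
    row (-inf for genera beyond every tie, kept finite as the global max
    distance plus one for downstream arithmetic).
    """
    distances = np.asarray(distances, dtype=np.float64)
    if distances.size == 0:
        raise ValueError("empty reference set")
    d_min = distances.min()
    tied = np.flatnonzero(distances - d_min <= TIE_RTOL * max(1.0, d_min))
    tied_genera = np.unique(row_genus[tied])
    # per-genus best distance as a score vector (higher = closer)
    z = np.full(len(genera), -(distances.max() + 1.0))
    np.maximum.at(z, row_genus, -distances)
    genus = genera[tied_genera[0]] if tied_genera.size == 1 else UNCLASSIFIED
    return GenusAssignment(genus=genus, scores=z, method=method)


def classify_nn(model: NnModel, query: CountVector, method: str = "nn") -> GenusAssignment:
    """Assign the genus of the Euclidean-nearest training profile."""
    if query.mode != "profile":
        raise ValueError(f"classify_nn expects mode='profile', got {query.mode!r}")
    _check_dim(model.profiles, query.values)
    diff = model.profiles - query.values[None, :]
    distances = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return nearest_genus(distances, model.row_genus, model.genera, method=method)


def classify_record(model, record, dictionary: KmerDictionary, priors=None) -> GenusAssignment:
    """Convenience one-record classification for any trained model type."""
    from .kmers import to_presence, to_profile  # local to avoid cycles in doc order

    freq = count_kmers(record, dictionary)
    if freq.values.sum() == 0:
        g = len(model.genera)
        return GenusAssignment(genus=UNCLASSIFIED, scores=np.zeros(g), method="")
    if isinstance(model, RdpModel):
        return assign_from_scores(score_rdp(model, to_presence(freq), priors), model.genera, "rdp")
    if isinstance(model, MultinomialModel):
        return assign_from_scores(
            score_multinomial(model, freq, priors), model.genera, "multinomial"
        )
    if isinstance(model, MarkovModel):
        return assign_from_scores(score_markov(model, freq), model.genera, "markov")
    if isinstance(model, NnModel):
        return classify_nn(model, to_profile(freq))
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# batch scoring (used by the cross-validation harness)
# ---------------------------------------------------------------------------


def classify_counts(model, counts: np.ndarray, priors=None, method: str = "") -> list[GenusAssignment]:
    """Classify many query frequency rows at once.

    Queries with zero countable K-mers are returned unclassified for every
    method (no evidence to rank genera on).
    """
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1)
    n_genera = len(model.genera)

    if isinstance(model, RdpModel):
        z_all = presence_matrix(counts) @ model.log_q.T
        if priors is not None:
            z_all = z_all + priors[None, :]
        method = method or "rdp"
    elif isinstance(model, MultinomialModel):
        z_all = counts @ model.log_q.T
        if priors is not None:
            z_all = z_all + priors[None, :]
        method = method or "multinomial"
    elif isinstance(model, MarkovModel):
        z_all = counts @ model.log_q.T
        method = method or "markov"
    elif isinstance(model, NnModel):
        method = method or "nn"
        profiles = profile_matrix(counts)
        # squared Euclidean distances via the expansion trick
        d2 = (
            np.einsum("ij,ij->i", profiles, profiles)[:, None]
            + np.einsum("ij,ij->i", model.profiles, model.profiles)[None, :]
            - 2.0 * profiles @ model.profiles.T
        )
        dists = np.sqrt(np.clip(d2, 0.0, None))
        out = []
        for i in range(counts.shape[0]):
            if totals[i] == 0:
                out.append(GenusAssignment(UNCLASSIFIED, np.zeros(n_genera), method))
            else:
                out.append(nearest_genus(dists[i], model.row_genus, model.genera, method))
        return out
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    out = []
    for i in range(counts.shape[0]):
        if totals[i] == 0:
            out.append(GenusAssignment(UNCLASSIFIED, np.zeros(n_genera), method))
        else:
            out.append(assign_from_scores(z_all[i], model.genera, method))
    return out
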