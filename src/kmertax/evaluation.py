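"""Benchmarking protocol: 10-fold cross-validation, fragmentation, error metrics.

The protocol mirrors standard practice for genus-level 16S benchmarks:

* Folds: records are ordered alphabetically by genus (ties broken by id) and
  dealt round-robin into ten segments, so every genus is spread across as
  many folds as it has sequences.  Each segment serves once as the test set.
* Singleton genera (one sequence in the whole corpus) are necessarily
  misclassified — their genus is absent from training when they are tested —
  so all reported errors exclude them.
* An ``unclassified`` outcome counts as an error.
* Fragment mode chops every test sequence into ``n_fragments`` partially
  overlapping windows of ``frag_len`` bases (start offsets evenly spaced,
  endpoints pinned to the sequence ends) and classifies every fragment as an
  independent query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .kmers import KmerDictionary, SequenceRecord, count_matrix
from .classifiers import (
    UNCLASSIFIED,
    GenusAssignment,
    classify_counts,
    compute_log_priors,
    genus_sizes_from_labels,
    markov_from_counts,
    multinomial_from_counts,
    nn_from_counts,
    rdp_from_counts,
)
from .pls import classify_plsnn_counts, dimension_grid, plsnn_from_counts

logger = logging.getLogger("kmertax")

METHODS = ("rdp", "multinomial", "markov", "nn", "plsnn")


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregated classification errors with singleton exclusion applied."""

    n_evaluated: int
    n_errors: int
    n_unclassified: int
    n_singletons_excluded: int

    @property
    def error_pct(self) -> float:
        """Percent misclassified among evaluated (non-singleton) queries."""
        if self.n_evaluated == 0:
            return float("nan")
        return 100.0 * self.n_errors / self.n_evaluated


@dataclass
class Prediction:
    """One classified query within a cross-validation run."""

    seq_id: str
    truth: str
    predicted: str
    fold: int
    fragment: Optional[int] = None  # 1-based fragment index, None in full mode


@dataclass
class CvResult:
    """Outcome of one method x K cross-validation run."""

    method: str
    k: int
    mode: str  # "full" | "fragments"
    fold_summaries: list[ErrorSummary]
    pooled: ErrorSummary
    predictions: list[Prediction]
    singleton_genera: set[str] = field(default_factory=set)

    def error_ids(self) -> set[str]:
        """Ids of misclassified non-singleton queries (fragment-qualified)."""
        out = set()
        for p in self.predictions:
            if p.truth in self.singleton_genera:
                continue
            if p.predicted != p.truth:
                key = p.seq_id if p.fragment is None else f"{p.seq_id}#{p.fragment}"
                out.add(key)
        return out


def make_cv_folds(records: Sequence[SequenceRecord], n_folds: int = 10) -> np.ndarray:
    """Fold index 1..n_folds per record, aligned with the input order.

    Records are sorted by (genus, id) and dealt round-robin, which maximally
    spreads each genus across folds: a genus of size s <= n_folds lands in s
    distinct folds.
    """
    for r in records:
        if not r.genus:
            raise ValueError(f"record {r.id!r} has no genus label")
    order = sorted(range(len(records)), key=lambda i: (records[i].genus, records[i].id))
    folds = np.empty(len(records), dtype=np.int64)
    for rank, i in enumerate(order):
        folds[i] = rank % n_folds + 1
    return folds


def fragment_sequence(seq, n_fragments: int = 10, frag_len: int = 200) -> list[str]:
    """Partially overlapping fragments spanning the whole sequence.

    Start offsets are evenly spaced, start_i = round((i-1)(L-frag_len)/(n-1)),
    so fragment 1 begins at the first base and the last fragment ends at the
    last base.  A sequence no longer than ``frag_len`` yields n identical
    copies of itself (fully degenerate overlap).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    L = len(residues)
    if L <= frag_len:
        if L < frag_len:
            logger.warning("sequence shorter than fragment length (%d < %d)", L, frag_len)
        return [residues] * n_fragments
    span = L - frag_len
    starts = [int(np.floor(i * span / (n_fragments - 1) + 0.5)) for i in range(n_fragments)]
    return [residues[s : s + frag_len] for s in starts]


def singleton_genera(records: Sequence[SequenceRecord]) -> set[str]:
    """Genera represented by exactly one sequence in the corpus."""
    sizes: dict[str, int] = {}
    for r in records:
        sizes[r.genus] = sizes.get(r.genus, 0) + 1
    return {g for g, n in sizes.items() if n == 1}


def _predicted_name(a) -> str:
    return a.genus if isinstance(a, GenusAssignment) else str(a)


def classification_error(
    assignments: Sequence,
    truth: Sequence[str],
    singletons: set[str] = frozenset(),
) -> ErrorSummary:
    """Error summary over aligned predictions and true genera.

    Queries whose true genus is a singleton are excluded from evaluation;
    among the rest, a wrong genus or ``unclassified`` counts as an error.
    """
    if len(assignments) != len(truth):
        raise ValueError(f"{len(assignments)} assignments vs {len(truth)} truths")
    n_eval = n_err = n_uncl = n_excl = 0
    for a, t in zip(assignments, truth):
        pred = _predicted_name(a)
        if t in singletons:
            n_excl += 1
            continue
        n_eval += 1
        if pred == UNCLASSIFIED:
            n_uncl += 1
            n_err += 1
        elif pred != t:
            n_err += 1
    return ErrorSummary(n_eval, n_err, n_uncl, n_excl)


def error_by_genus_size(
    assignments: Sequence,
    truth: Sequence[str],
    genus_sizes: Mapping[str, int],
    max_size: int = 10,
) -> dict[int, float]:
    """Mean per-genus error percent, by genus size 2..max_size.

    Sizes come from the full corpus, not the training split.  For each size,
    the per-genus error percentage is computed first and then averaged across
    all genera of that size; sizes with no genera are absent from the table.
    """
    per_genus: dict[str, list[int]] = {}
    for a, t in zip(assignments, truth):
        per_genus.setdefault(t, []).append(int(_predicted_name(a) != t))
    by_size: dict[int, list[float]] = {}
    for genus, outcomes in per_genus.items():
        size = genus_sizes.get(genus)
        if size is None or not 2 <= size <= max_size:
            continue
        by_size.setdefault(size, []).append(100.0 * sum(outcomes) / len(outcomes))
    return {s: float(np.mean(v)) for s, v in sorted(by_size.items())}


def error_set_overlap(
    error_sets: Mapping[str, set],
    assignments: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> tuple[dict[tuple[str, ...], int], Optional[int]]:
    """Venn sector counts of per-method error id sets.

    Returns the count of ids falling in each non-empty sector (keyed by the
    sorted tuple of methods whose error sets contain exactly those ids) and,
    when per-method assignments are supplied, how many ids in the all-methods
    sector received the identical wrong genus from every method.
    """
    methods = sorted(error_sets)
    if len(methods) > 6:
        raise ValueError("overlap reporting supports at most 6 methods")
    universe = set().union(*error_sets.values()) if error_sets else set()
    sectors: dict[tuple[str, ...], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            inside = set(universe)
            for m in combo:
                inside &= error_sets[m]
            for m in methods:
                if m not in combo:
                    inside -= error_sets[m]
            sectors[combo] = len(inside)

    n_identical = None
    if assignments is not None and methods:
        center = set(universe)
        for m in methods:
            center &= error_sets[m]
        n_identical = 0
        for q in center:
            calls = {assignments[m].get(q) for m in methods}
            if len(calls) == 1:
                n_identical += 1
    return sectors, n_identical


def positional_error(
    fragment_indices: Sequence[int],
    assignments: Sequence,
    truth: Sequence[str],
    singletons: set[str] = frozenset(),
    n_fragments: int = 10,
) -> np.ndarray:
    """Error percent per fragment position 1..n_fragments."""
    err = np.zeros(n_fragments)
    tot = np.zeros(n_fragments)
    for idx, a, t in zip(fragment_indices, assignments, truth):
        if t in singletons:
            continue
        tot[idx - 1] += 1
        if _predicted_name(a) != t:
            err[idx - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * err / tot


def _train(method: str, counts: np.ndarray, labels: Sequence[str], k: int,
           n_components: Optional[int]):
    if method == "rdp":
        return rdp_from_counts(counts, labels, k)
    if method == "multinomial":
        return multinomial_from_counts(counts, labels, k)
    if method == "markov":
        return markov_from_counts(counts, labels, k)
    if method == "nn":
        return nn_from_counts(counts, labels, k)
    if method == "plsnn":
        if n_components is None:
            n_components = dimension_grid(len(labels), k)[0]
        return plsnn_from_counts(counts, labels, k, n_components)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_cross_validation(
    records: Sequence[SequenceRecord],
    method: str,
    k: int,
    *,
    priors: str = "flat",
    mode: str = "full",
    n_components: Optional[int] = None,
    n_folds: int = 10,
    n_fragments: int = 10,
    frag_len: int = 200,
) -> CvResult:
    """Cross-validate one method at one word length.

    Trains on n_folds - 1 segments and tests on the held-out one, rotating.
    In ``fragments`` mode every test sequence contributes ``n_fragments``
    windows of ``frag_len`` bases, each classified independently.  The run is
    deterministic given the records and options.
    """
    if mode not in ("full", "fragments"):
        raise ValueError(f"mode must be 'full' or 'fragments', got {mode!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    dictionary = KmerDictionary(k)
    folds = make_cv_folds(records, n_folds)
    singletons = singleton_genera(records)
    full_counts = count_matrix(records, dictionary)

    predictions: list[Prediction] = []
    fold_summaries: list[ErrorSummary] = []
    for f in range(1, n_folds + 1):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        if test_idx.size == 0:
            fold_summaries.append(ErrorSummary(0, 0, 0, 0))
            continue
        train_labels = [records[i].genus for i in train_idx]
        model = _train(method, full_counts[train_idx], train_labels, k, n_components)
        p = None
        if method in ("rdp", "multinomial"):
            sizes = genus_sizes_from_labels(train_labels, model.genera)
            p = compute_log_priors(sizes, priors)

        if mode == "full":
            query_counts = full_counts[test_idx]
            meta = [(records[i].id, records[i].genus, None) for i in test_idx]
        else:
            frag_seqs, meta = [], []
            for i in test_idx:
                for j, frag in enumerate(
                    fragment_sequence(records[i], n_fragments, frag_len), start=1
                ):
                    frag_seqs.append(frag)
                    meta.append((records[i].id, records[i].genus, j))
            query_counts = count_matrix(frag_seqs, dictionary)

        if method == "plsnn":
            assigned = classify_plsnn_counts(model, query_counts)
        else:
            assigned = classify_counts(model, query_counts, priors=p)

        fold_preds = [
            Prediction(seq_id=sid, truth=t, predicted=a.genus, fold=f, fragment=frag)
            for (sid, t, frag), a in zip(meta, assigned)
        ]
        predictions.extend(fold_preds)
        fold_summaries.append(
            classification_error(
                [p_.predicted for p_ in fold_preds],
                [p_.truth for p_ in fold_preds],
                singletons,
            )
        )

    pooled = ErrorSummary(
        n_evaluated=sum(s.n_evaluated for s in fold_summaries),
        n_errors=sum(s.n_errors for s in fold_summaries),
        n_unclassified=sum(s.n_unclassified for s in fold_summaries),
        n_singletons_excluded=sum(s.n_singletons_excluded for s in fold_summaries),
    )
    logger.info(
        "CV %s K=%d mode=%s: %.2f%% error (%d/%d, %d unclassified, %d singletons excluded)",
        method, k, mode, pooled.error_pct, pooled.n_errors, pooled.n_evaluated,
        pooled.n_unclassified, pooled.n_singletons_excluded,
    )
    return CvResult(
        method=method,
        k=k,
        mode=mode,
        fold_summaries=fold_summaries,
        pooled=pooled,
        predictions=predictions,
        singleton_genera=singletons,
    )
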