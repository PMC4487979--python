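"""File I/O: FASTA + label tables, assignment tables, model persistence.

Two labelling dialects are supported: an external two-column TSV mapping
sequence id to genus, and RDP-style headers whose description carries a
semicolon-separated lineage (``id<TAB>Root;...;Genus``) from which the last
non-empty rank is taken as the genus.

Trained models persist as NumPy ``.npz`` containers with a version field;
files written by a newer format version are refused rather than misread.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .kmers import SequenceRecord
from .classifiers import (
    GenusAssignment,
    MarkovModel,
    MultinomialModel,
    NnModel,
    RdpModel,
)
from .pls import PlsFit, PlsnnModel

logger = logging.getLogger("kmertax")

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a persisted model cannot be understood."""


def read_label_table(path) -> dict[str, str]:
    """Parse a two-column TSV of sequence id -> genus."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>genus', got {line!r}")
            if parts[0] in labels:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {parts[0]!r}")
            labels[parts[0]] = parts[1]
    return labels


def _genus_from_lineage(description: str) -> Optional[str]:
    """Last non-empty rank of an RDP-style 'id<TAB>Root;...;Genus' header."""
    for sep in ("\t", " "):
        if sep in description:
            lineage = description.split(sep, 1)[1]
            ranks = [r.strip() for r in lineage.split(";")]
            ranks = [r for r in ranks if r]
            if ranks:
                return ranks[-1]
    return None


def read_labeled_fasta(
    fasta_path,
    labels_path=None,
    header_lineage: bool = False,
) -> list[SequenceRecord]:
    """Read FASTA records, attaching genus labels.

    With ``labels_path``, labels come from an external TSV and every id must
    be covered; with ``header_lineage=True``, the genus is the last non-empty
    rank of the header lineage.  With neither, records are unlabelled.
    Duplicate ids are a hard error.
    """
    label_map = read_label_table(labels_path) if labels_path is not None else None
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    missing: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        genus = None
        if label_map is not None:
            genus = label_map.get(rec.id)
            if genus is None:
                missing.append(rec.id)
        elif header_lineage:
            genus = _genus_from_lineage(rec.description)
            if genus is None:
                missing.append(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), genus=genus))
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"no genus label for sequence ids: {shown}{more}")
    logger.info("read %d records from %s", len(records), fasta_path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), 70):
                fh.write(r.residues[i : i + 70] + "\n")


def write_labels(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.genus}\n")


ASSIGNMENT_COLUMNS = ("query_id", "method", "K", "genus", "top_score", "margin")


def write_assignments(rows: Sequence[tuple[str, str, int, GenusAssignment]], path) -> None:
    """Write a TSV of classifications: id, method, K, genus, top score, margin.

    ``margin`` is the gap between the best and second-best score (0 when only
    one genus exists).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for query_id, method, k, a in rows:
            z = np.sort(np.asarray(a.scores, dtype=np.float64))[::-1]
            top = z[0] if z.size else float("nan")
            margin = (z[0] - z[1]) if z.size > 1 else 0.0
            fh.write(f"{query_id}\t{method}\t{k}\t{a.genus}\t{top:.10g}\t{margin:.10g}\n")


def read_assignments(path) -> list[dict]:
    """Parse a written assignment table back into dict rows."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ASSIGNMENT_COLUMNS:
            raise ValueError(f"unexpected assignment header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                dict(
                    query_id=f[0], method=f[1], K=int(f[2]), genus=f[3],
                    top_score=float(f[4]), margin=float(f[5]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

_KIND_BY_TYPE = {
    RdpModel: "rdp",
    MultinomialModel: "multinomial",
    MarkovModel: "markov",
    NnModel: "nn",
    PlsnnModel: "plsnn",
}


def save_model(model, path) -> None:
    """Persist any trained model to a versioned .npz container."""
    kind = _KIND_BY_TYPE.get(type(model))
    if kind is None:
        raise TypeError(f"cannot persist model of type {type(model).__name__}")
    payload: dict[str, np.ndarray] = {
        "format_version": np.array(MODEL_FORMAT_VERSION),
        "kind": np.array(kind),
        "k": np.array(model.k),
        "genera": np.array(model.genera, dtype="U"),
    }
    if kind in ("rdp", "multinomial", "markov"):
        payload["log_q"] = model.log_q
        if kind == "rdp":
            payload["word_prob"] = model.word_prob
    elif kind == "nn":
        payload["profiles"] = model.profiles
        payload["row_genus"] = model.row_genus
    else:  # plsnn
        payload["row_genus"] = model.row_genus
        payload["weights"] = model.fit.weights
        payload["scores"] = model.fit.scores
        payload["x_mean"] = model.fit.x_mean
        payload["n_components"] = np.array(model.fit.n_components)
        if model.fit.coef is not None:
            payload["coef"] = model.fit.coef
    np.savez(path, **payload)


def load_model(path):
    """Load a model persisted by :func:`save_model`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            if "format_version" not in data or "kind" not in data:
                raise ModelFormatError(f"{path} is not a kmertax model file")
            version = int(data["format_version"])
            if version > MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path} uses model format v{version}; this build reads up to "
                    f"v{MODEL_FORMAT_VERSION}"
                )
            kind = str(data["kind"])
            k = int(data["k"])
            genera = [str(g) for g in data["genera"]]
            if kind == "rdp":
                return RdpModel(genera, k, data["word_prob"], data["log_q"])
            if kind == "multinomial":
                return MultinomialModel(genera, k, data["log_q"])
            if kind == "markov":
                return MarkovModel(genera, k, data["log_q"])
            if kind == "nn":
                return NnModel(genera, k, data["profiles"], data["row_genus"])
            if kind == "plsnn":
                fit = PlsFit(
                    weights=data["weights"],
                    scores=data["scores"],
                    x_mean=data["x_mean"],
                    n_components=int(data["n_components"]),
                    coef=data["coef"] if "coef" in data else None,
                )
                return PlsnnModel(fit=fit, genera=genera, row_genus=data["row_genus"], k=k)
            raise ModelFormatError(f"{path} holds unknown model kind {kind!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # zipfile/np errors on truncated or foreign files
        raise ModelFormatError(f"could not read model file {path}: {exc}") from exc
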