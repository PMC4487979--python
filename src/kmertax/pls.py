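"""PLS dimension reduction and the PLS-preprocessed nearest-neighbour classifier.

The K-mer profile space has D = 4**K coordinates, most of them empty or
redundant at large K.  Partial least squares (PLS2, NIPALS algorithm) finds
C << D orthonormal directions R maximizing covariance between the profile
matrix X (N x D) and the genus indicator matrix Y (N x G), giving training
scores S = X_centered R (N x C).  Classification projects a query profile
into the subspace, s = (a - mean) R, and runs the same Euclidean
nearest-neighbour rule as the full-space NN method over the rows of S.

Components are extracted sequentially with X-deflation; the weight vectors
are unit-norm and mutually orthogonal, so R'R = I.  Columns of X and Y are
mean-centered before fitting (no variance scaling: profiles already share a
common scale).  Extraction stops early, with a warning, when the residual X
variance drops below 1e-12 of its initial value (rank deficiency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kmers import KmerDictionary, CountVector, count_matrix, profile_matrix
from .classifiers import GenusAssignment, _check_labels, _genus_table, nearest_genus

logger = logging.getLogger("kmertax")

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000
_RESIDUAL_STOP = 1e-12


def indicator_matrix(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """0/1 genus membership matrix Y (N x G); each row sums to exactly 1."""
    labels = _check_labels(labels)
    genera, row_genus = _genus_table(labels)
    y = np.zeros((len(labels), len(genera)))
    y[np.arange(len(labels)), row_genus] = 1.0
    return y, genera


def dimension_grid(n_samples: int, k: int) -> list[int]:
    """The eight candidate subspace dimensions C = i * C_max / 8, i = 1..8.

    C_max = min(N - 1, 4**K - 1, 2000); grid values are rounded, clipped to
    >= 1 and deduplicated.
    """
    if n_samples < 2:
        raise ValueError("need at least two training sequences to fit a subspace")
    c_max = min(n_samples - 1, 4 ** k - 1, 2000)
    grid = sorted({max(1, int(np.floor(i * c_max / 8 + 0.5))) for i in range(1, 9)})
    return grid


@dataclass(frozen=True)
class PlsFit:
    """A fitted PLS2 mapping from profile space to a C-dimensional subspace."""

    weights: np.ndarray  # R, (D x C), orthonormal columns
    scores: np.ndarray  # S, (N x C) training scores
    x_mean: np.ndarray  # column means used for centering, length D
    n_components: int  # components actually extracted (<= requested C)
    coef: Optional[np.ndarray] = None  # regression coefficients (diagnostic only)


@dataclass(frozen=True)
class PlsnnModel:
    fit: PlsFit
    genera: list[str]
    row_genus: np.ndarray  # genus index per training row / score row
    k: int


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PlsFit:
    """Fit PLS2 by NIPALS with X-deflation.

    Returns orthonormal weights R and scores S with X_centered @ R ~= S.
    Raises for C > min(N - 1, D); rank-deficient X stops early with fewer
    components (recorded in ``n_components``).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, d = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    if not 1 <= n_components <= min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} not in [1, min(N-1, D)] = [1, {min(n - 1, d)}]"
        )

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - Y.mean(axis=0)
    initial_var = np.einsum("ij,ij->", Xc, Xc)

    w_cols, t_cols, p_cols, q_cols = [], [], [], []
    for c in range(n_components):
        residual = np.einsum("ij,ij->", Xc, Xc)
        if initial_var == 0 or residual < _RESIDUAL_STOP * initial_var:
            logger.warning(
                "PLS extraction stopped at %d of %d components (X residual exhausted)",
                c,
                n_components,
            )
            break
        # start u from the Y column with most remaining variance
        u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
        if not np.any(u):
            u = Yc[:, 0].copy()
        t = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = Xc.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                break
            w /= norm_w
            t_new = Xc @ w
            q = Yc.T @ t_new / (t_new @ t_new)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt == 0 or norm_w == 0:
            logger.warning("PLS component %d degenerate; stopping extraction", c + 1)
            break
        p = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc -= np.outer(t, p)
        Yc -= np.outer(t, q)
        w_cols.append(w)
        t_cols.append(t)
        p_cols.append(p)
        q_cols.append(q)

    if not w_cols:
        raise ValueError("could not extract any PLS component (X has no variance)")

    W = np.column_stack(w_cols)
    T = np.column_stack(t_cols)
    P = np.column_stack(p_cols)
    Q = np.column_stack(q_cols)
    # beta of the linear model E(Y) = X beta, for diagnostics
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PlsFit(weights=W, scores=T, x_mean=x_mean, n_components=W.shape[1], coef=coef)


def project(fit: PlsFit, a) -> np.ndarray:
    """Subspace coordinates s = (a - training column means) R.

    Accepts a profile :class:`CountVector`, a 1-D array, or a 2-D batch.
    """
    if isinstance(a, CountVector):
        if a.mode != "profile":
            raise ValueError(f"project expects mode='profile', got {a.mode!r}")
        values = a.values
    else:
        values = np.asarray(a, dtype=np.float64)
    if values.shape[-1] != fit.x_mean.size:
        raise ValueError(
            f"query dimension {values.shape[-1]} does not match fit D={fit.x_mean.size}"
        )
    return (values - fit.x_mean) @ fit.weights


def plsnn_from_counts(counts: np.ndarray, labels: Sequence[str], k: int, n_components: int) -> PlsnnModel:
    labels = _check_labels(labels)
    totals = np.asarray(counts).sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        logger.warning("skipping %d degenerate training sequences", int((~keep).sum()))
    kept_labels = [g for g, ok in zip(labels, keep) if ok]
    X = profile_matrix(np.asarray(counts)[keep])
    Y, genera = indicator_matrix(kept_labels)
    _, row_genus = _genus_table(kept_labels)
    fit = fit_pls(X, Y, n_components)
    return PlsnnModel(fit=fit, genera=genera, row_genus=row_genus, k=k)


def train_plsnn(training, dictionary: KmerDictionary, n_components: int) -> PlsnnModel:
    """Fit the PLS subspace on training profiles and keep the projected rows."""
    labels = _check_labels([r.genus for r in training])
    counts = count_matrix(training, dictionary)
    return plsnn_from_counts(counts, labels, dictionary.k, n_components)


def classify_plsnn(model: PlsnnModel, query: CountVector) -> GenusAssignment:
    """Nearest neighbour over the projected training scores."""
    s = project(model.fit, query)
    diff = model.fit.scores - s[None, :]
    distances = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return nearest_genus(distances, model.row_genus, model.genera, method="plsnn")


def classify_plsnn_counts(model: PlsnnModel, counts: np.ndarray) -> list[GenusAssignment]:
    """Batch PLSNN classification of query frequency rows."""
    from .classifiers import UNCLASSIFIED

    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1)
    S = project(model.fit, profile_matrix(counts))
    d2 = (
        np.einsum("ij,ij->i", S, S)[:, None]
        + np.einsum("ij,ij->i", model.fit.scores, model.fit.scores)[None, :]
        - 2.0 * S @ model.fit.scores.T
    )
    dists = np.sqrt(np.clip(d2, 0.0, None))
    out = []
    for i in range(counts.shape[0]):
        if totals[i] == 0:
            out.append(GenusAssignment(UNCLASSIFIED, np.zeros(len(model.genera)), "plsnn"))
        else:
            out.append(nearest_genus(dists[i], model.row_genus, model.genera, "plsnn"))
    return out
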