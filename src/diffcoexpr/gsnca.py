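"""Network weight vectors and differential co-expression statistics.

A gene set's co-expression network is summarised by a per-gene weight
vector: each gene's weight equals the sum of its weighted absolute
correlations with the other genes, w_i = sum_{j != i} w_j |r_ij|, which is
the leading (Perron) eigenvector of the matrix A with A_ij = |r_ij| off the
diagonal and A_ii = 0. Absolute correlations make A entrywise nonnegative so
the leading eigenvector is nonnegative and essentially unique.

The differential statistic between two conditions is the L1 distance between
the two scaled weight vectors (scaled to mean 1),

    W = sum_i | w_i,norm(1) - w_i,norm(2) |,

a nonnegative distance that is 0 iff the two network weightings agree.
The dispersion baseline aggregates raw pairwise correlation changes:
sqrt( mean over pairs of (r1_ij - r2_ij)^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["WeightVector", "weight_vector", "gsnca_statistic", "gsca_statistic"]

_EIG_TIE_TOL = 1e-10


class DegenerateInputError(ValueError):
    """Raised when a correlation matrix cannot support a weight vector."""


@dataclass
class WeightVector:
    genes: list[str]
    w_raw: np.ndarray
    w_norm: np.ndarray
    eigenvalue: float
    degenerate_spectrum: bool = False


def _drop_missing(r: np.ndarray, genes: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove genes with any undefined (NaN) off-diagonal correlation."""
    r = np.asarray(r, dtype=float)
    off = r.copy()
    np.fill_diagonal(off, 0.0)
    keep = ~np.any(np.isnan(off), axis=1)
    if keep.all():
        return r, list(genes)
    kept = np.flatnonzero(keep)
    return r[np.ix_(kept, kept)], [genes[i] for i in kept]


def weight_vector(r: np.ndarray, genes: list[str] | None = None) -> WeightVector:
    """Leading-eigenvector gene weights of the absolute correlation matrix.

    Genes with any missing correlation are removed first; at least 3 genes
    must remain. Weights are oriented nonnegative and scaled so that their
    mean is exactly 1 (w_norm = p * w_raw / sum(w_raw)). A gene disconnected
    from the rest (all |r| = 0) keeps weight 0.
    """
    r = np.asarray(r, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(r.shape[0])]
    if r.shape[0] != r.shape[1] or r.shape[0] != len(genes):
        raise ValueError("correlation matrix and gene list sizes disagree")
    r, genes = _drop_missing(r, list(genes))
    p = r.shape[0]
    if p < 3:
        raise DegenerateInputError(
            f"need >= 3 genes with defined correlations, have {p}"
        )
    A = np.abs(r)
    np.fill_diagonal(A, 0.0)
    if not np.any(A > 0):
        raise DegenerateInputError("all correlations are zero; weights undefined")
    evals, evecs = scipy.linalg.eigh(A)
    lam = float(evals[-1])
    w = evecs[:, -1]
    degenerate = bool(p >= 2 and (evals[-1] - evals[-2]) < _EIG_TIE_TOL)
    # Perron orientation: make the dominant sign positive, clip fp noise
    if w.sum() < 0:
        w = -w
    w = np.where(np.abs(w) < 1e-14, 0.0, w)
    w = np.maximum(w, 0.0)
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("degenerate leading eigenvector")
    w_norm = p * w / total
    return WeightVector(
        genes=genes, w_raw=w, w_norm=w_norm, eigenvalue=lam,
        degenerate_spectrum=degenerate,
    )


def gsnca_statistic(w1: WeightVector, w2: WeightVector) -> float:
    """L1 distance between two scaled weight vectors over identical genes."""
    if w1.genes != w2.genes:
        raise ValueError("weight vectors are over different gene lists")
    return float(np.sum(np.abs(w1.w_norm - w2.w_norm)))


def gsca_statistic(r1: np.ndarray, r2: np.ndarray) -> float:
    """Root-mean-square pairwise correlation difference (dispersion index)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape or r1.shape[0] != r1.shape[1]:
        raise ValueError("correlation matrices must be square and same shape")
    p = r1.shape[0]
    iu = np.triu_indices(p, k=1)
    d = r1[iu] - r2[iu]
    return float(np.sqrt(np.nanmean(d * d)))
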