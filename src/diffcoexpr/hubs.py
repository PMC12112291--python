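"""Hub-gene ranking by weighted node connectivity (WNC).

A gene's WNC in a condition network is the sum of its absolute correlations
with the other genes of the set; in the differential network it is the sum
of absolute correlation differences over the edges retained by the
threshold (|r1 - r2| > edge_threshold, default 0.2). Condition networks are
unthresholded. Genes are ranked by differential WNC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HubTable", "wnc_scores", "export_edges"]

_SYM_TOL = 1e-8


@dataclass
class HubTable:
    genes: list[str]            # ordered by wnc_diff descending, ties by gene ID
    wnc_cond1: np.ndarray
    wnc_cond2: np.ndarray
    wnc_diff: np.ndarray
    wnc_diff_raw: np.ndarray    # unthresholded differential sums
    edge_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "wnc_cond1": self.wnc_cond1,
                "wnc_cond2": self.wnc_cond2,
                "wnc_diff": self.wnc_diff,
                "wnc_diff_raw": self.wnc_diff_raw,
            }
        )


def _check_pair(r1: np.ndarray, r2: np.ndarray, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape or r1.shape[0] != r1.shape[1]:
        raise ValueError("correlation matrices must be square and of equal shape")
    if len(genes) != r1.shape[0]:
        raise ValueError("gene list length must match matrix size")
    for name, r in (("r1", r1), ("r2", r2)):
        delta = np.nanmax(np.abs(r - r.T), initial=0.0)
        if delta > _SYM_TOL:
            raise ValueError(f"{name} is not symmetric (max asymmetry {delta:.2e})")
    return r1, r2


def wnc_scores(
    r1: np.ndarray,
    r2: np.ndarray,
    genes: list[str] | None = None,
    edge_threshold: float = 0.2,
) -> HubTable:
    """Per-gene WNC in condition 1, condition 2 and the differential network.

    Missing correlations (NaN) contribute 0 to every sum. Only the
    differential network is thresholded; condition sums are unthresholded.
    """
    if genes is None:
        genes = [f"g{i}" for i in range(np.asarray(r1).shape[0])]
    r1, r2 = _check_pair(r1, r2, list(genes))
    a1 = np.abs(r1).copy()
    a2 = np.abs(r2).copy()
    np.fill_diagonal(a1, 0.0)
    np.fill_diagonal(a2, 0.0)
    d = np.abs(r1 - r2)
    np.fill_diagonal(d, 0.0)
    wnc1 = np.nansum(a1, axis=1)
    wnc2 = np.nansum(a2, axis=1)
    wnc_diff_raw = np.nansum(d, axis=1)
    d_thr = np.where(d > edge_threshold, d, 0.0)
    wnc_diff = np.nansum(d_thr, axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-wnc_diff[i], genes[i]))
    return HubTable(
        genes=[genes[i] for i in order],
        wnc_cond1=wnc1[order],
        wnc_cond2=wnc2[order],
        wnc_diff=wnc_diff[order],
        wnc_diff_raw=wnc_diff_raw[order],
        edge_threshold=edge_threshold,
    )


def export_edges(
    r1: np.ndarray,
    r2: np.ndarray,
    genes: list[str] | None = None,
    edge_threshold: float = 0.2,
) -> pd.DataFrame:
    """Edge list of pairs with |r1 - r2| > edge_threshold.

    One row per unordered pair, gene_a < gene_b lexicographically, columns
    gene_a, gene_b, r1, r2, diff.
    """
    if genes is None:
        genes = [f"g{i}" for i in range(np.asarray(r1).shape[0])]
    r1, r2 = _check_pair(r1, r2, list(genes))
    p = len(genes)
    rows = []
    ia, ib = np.triu_indices(p, k=1)
    diff = r1[ia, ib] - r2[ia, ib]
    keep = np.abs(diff) > edge_threshold
    for i, j, dv in zip(ia[keep], ib[keep], diff[keep]):
        ga, gb = genes[i], genes[j]
        if gb < ga:
            ga, gb = gb, ga
        rows.append(
            {"gene_a": ga, "gene_b": gb, "r1": r1[i, j], "r2": r2[i, j], "diff": dv}
        )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r1", "r2", "diff"])
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
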