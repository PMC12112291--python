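"""Permutation tests for differential gene-set co-expression.

Workflow: balance the two conditions to equal cell numbers, estimate a
within-condition co-expression network for the tested gene set under each
condition, summarise the difference with a single nonnegative statistic,
and calibrate it against a permutation null obtained by shuffling the cell
condition labels.

Three methods share this scaffold and differ only in the correlation
backend and statistic:

* ``gsncascr``      — Poisson measurement-model (IRLS) correlations feeding
                      the eigenvector-weight L1 statistic;
* ``gsnca_pearson`` — Pearson correlations of depth-normalised log counts
                      feeding the same L1 statistic;
* ``gsca``          — Pearson correlations feeding the root-mean-square
                      pairwise correlation-difference statistic.

Permutation statistics are approximately normal (checked per set with a
Shapiro-Wilk diagnostic), so the default p-value fits N(mean, sd) to the
permutation sample and takes the upper tail; an empirical (k+1)/(n+1)
tail is available as an alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneSetCollection, ValidationError
from .cscore import _fit_cscore_array, estimate_depths
from .gsnca import DegenerateInputError, gsca_statistic, gsnca_statistic, weight_vector

__all__ = [
    "PathwayTestResult",
    "balance_cells",
    "permutation_test",
    "run_pathway_scan",
    "results_to_frame",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("gsncascr", "gsnca_pearson", "gsca")


@dataclass
class PathwayTestResult:
    pathway: str
    method: str
    n_genes_used: int
    statistic: float
    perm_mean: float
    perm_sd: float
    n_perm: int
    pvalue: float
    pvalue_adj: float | None = None
    seed: int = 0
    shapiro_p: float | None = None
    degenerate_spectrum: bool = False
    # log10 of the p-value computed in log space: for extreme statistics the
    # normal tail underflows double precision, but the ranking stays defined
    log10_pvalue: float = 0.0


def results_to_frame(results: list[PathwayTestResult]) -> pd.DataFrame:
    cols = [
        "pathway", "method", "n_genes_used", "statistic", "perm_mean",
        "perm_sd", "n_perm", "pvalue", "pvalue_adj", "shapiro_p", "seed",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def balance_cells(cm: CountMatrix, seed: int) -> CountMatrix:
    """Downsample the larger condition to the smaller one's cell count."""
    lev_a, lev_b = cm.condition_levels()
    idx_a = np.flatnonzero(cm.condition == lev_a)
    idx_b = np.flatnonzero(cm.condition == lev_b)
    if min(len(idx_a), len(idx_b)) < 10:
        raise ValidationError(
            f"too few cells for estimation: {lev_a}={len(idx_a)}, {lev_b}={len(idx_b)}"
        )
    rng = np.random.default_rng(seed)
    k = min(len(idx_a), len(idx_b))
    keep_a = np.sort(rng.choice(idx_a, size=k, replace=False))
    keep_b = np.sort(rng.choice(idx_b, size=k, replace=False))
    rows = np.sort(np.concatenate([keep_a, keep_b]))
    return cm.subset_cells(rows)


def _log_normalise(X: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Per-cell depth normalisation to the median depth, then log1p."""
    scale = np.median(depths) / depths
    return np.log1p(X * scale[:, None])


def _pearson_by_condition(Y: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson correlation over cells ``rows``; constant genes give NaN."""
    sub = Y[rows]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    return np.asarray(r)


def _common_defined(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Boolean mask of genes with all off-diagonal entries defined in both."""
    bad = np.zeros(r1.shape[0], dtype=bool)
    for r in (r1, r2):
        off = r.copy()
        np.fill_diagonal(off, 0.0)
        bad |= np.any(np.isnan(off), axis=1)
    return ~bad


def _statistic_from_corrs(
    r1: np.ndarray, r2: np.ndarray, genes: list[str], method: str
) -> tuple[float, bool]:
    """Difference statistic on the genes defined in both conditions."""
    keep = _common_defined(r1, r2)
    if keep.sum() < 3:
        return float("nan"), False
    kept = np.flatnonzero(keep)
    r1 = r1[np.ix_(kept, kept)]
    r2 = r2[np.ix_(kept, kept)]
    genes = [genes[i] for i in kept]
    if method == "gsca":
        return gsca_statistic(r1, r2), False
    try:
        w1 = weight_vector(r1, genes)
        w2 = weight_vector(r2, genes)
    except DegenerateInputError:
        return float("nan"), False
    return gsnca_statistic(w1, w2), w1.degenerate_spectrum or w2.degenerate_spectrum


class _Backend:
    """Per-gene-set state reused across permutation replicates."""

    def __init__(self, cm: CountMatrix, genes: list[str], method: str,
                 max_iter: int = 10, tol: float = 1e-6):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.genes = genes
        self.depths = estimate_depths(cm)
        idx = cm.gene_index(genes)
        self.X = cm.counts[:, idx].astype(float)
        self.max_iter = max_iter
        self.tol = tol
        if method in ("gsnca_pearson", "gsca"):
            self.Y = _log_normalise(self.X, self.depths)

    def corr(self, rows: np.ndarray) -> np.ndarray:
        if self.method == "gsncascr":
            fit = _fit_cscore_array(
                self.X[rows], self.depths[rows], self.genes,
                max_iter=self.max_iter, tol=self.tol,
            )
            return fit.rho
        return _pearson_by_condition(self.Y, rows)

    def statistic(self, rows1: np.ndarray, rows2: np.ndarray) -> tuple[float, bool]:
        return _statistic_from_corrs(
            self.corr(rows1), self.corr(rows2), self.genes, self.method
        )


def permutation_test(
    cm: CountMatrix,
    geneset: list[str],
    method: str = "gsncascr",
    n_perm: int = 500,
    seed: int = 0,
    pvalue_mode: str = "normal_approx",
) -> PathwayTestResult:
    """Test one gene set for differential co-expression between conditions.

    ``cm`` should already be cell-balanced (see :func:`balance_cells`); the
    permutation null shuffles condition labels within it. The p-value is
    one-sided upper (larger statistic = more differential). ``pvalue_mode``
    "normal_approx" fits a normal to the permutation sample; "empirical"
    returns (k + 1) / (n_perm + 1) with k the count of permutation statistics
    >= the observed one.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if pvalue_mode not in ("normal_approx", "empirical"):
        raise ValueError(f"unknown pvalue_mode {pvalue_mode!r}")
    measured = set(cm.gene_ids)
    genes = [g for g in geneset if g in measured]
    if len(genes) < 3:
        raise ValidationError(
            f"gene set has {len(genes)} measured genes; need >= 3"
        )
    lev_a, lev_b = cm.condition_levels()
    labels = np.asarray(cm.condition)
    backend = _Backend(cm, genes, method)

    rows1 = np.flatnonzero(labels == lev_a)
    rows2 = np.flatnonzero(labels == lev_b)
    observed, degen = backend.statistic(rows1, rows2)
    if np.isnan(observed):
        raise DegenerateInputError(
            f"observed statistic undefined for set of {len(genes)} genes"
        )

    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    n = len(labels)
    for b in range(n_perm):
        perm = rng.permutation(n)
        p_rows1 = perm[: len(rows1)]
        p_rows2 = perm[len(rows1):]
        perms[b], _ = backend.statistic(p_rows1, p_rows2)
    perms = perms[~np.isnan(perms)]
    if len(perms) < 10:
        raise DegenerateInputError("too many degenerate permutation replicates")

    perm_mean = float(perms.mean())
    perm_sd = float(perms.std(ddof=1))
    shapiro_p = None
    if len(perms) >= 3 and perm_sd > 0:
        shapiro_p = float(stats.shapiro(perms).pvalue)

    mode = pvalue_mode
    if perm_sd == 0 and mode == "normal_approx":
        warnings.warn(
            "all permutation statistics identical; falling back to empirical p",
            RuntimeWarning,
            stacklevel=2,
        )
        mode = "empirical"
    if mode == "normal_approx":
        log10_pvalue = float(
            stats.norm.logsf(observed, loc=perm_mean, scale=perm_sd) / np.log(10.0)
        )
        pvalue = float(stats.norm.sf(observed, loc=perm_mean, scale=perm_sd))
        pvalue = max(pvalue, np.nextafter(0.0, 1.0))
    else:
        k = int(np.sum(perms >= observed))
        pvalue = (k + 1) / (len(perms) + 1)
        log10_pvalue = float(np.log10(pvalue))

    return PathwayTestResult(
        pathway="",
        method=method,
        n_genes_used=len(genes),
        statistic=float(observed),
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        n_perm=int(len(perms)),
        pvalue=pvalue,
        seed=seed,
        shapiro_p=shapiro_p,
        degenerate_spectrum=degen,
        log10_pvalue=log10_pvalue,
    )


def run_pathway_scan(
    cm: CountMatrix,
    sets: GeneSetCollection,
    method: str = "gsncascr",
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    pvalue_mode: str = "normal_approx",
    balance: bool = True,
) -> list[PathwayTestResult]:
    """Test every gene set in ``sets`` and BH-adjust across them.

    Cells are balanced once with the top-level ``seed``; each pathway uses a
    deterministically derived seed (seed + pathway index), so subsets of a
    collection can be run separately and merged. Sets with fewer than 3
    measured genes are logged and skipped. Results are ordered by p-value.
    """
    if balance:
        cm = balance_cells(cm, seed)
    results: list[PathwayTestResult] = []
    for i, (name, genes) in enumerate(sets.sets.items()):
        try:
            res = permutation_test(
                cm, genes, method=method, n_perm=n_perm,
                seed=seed + i, pvalue_mode=pvalue_mode,
            )
        except (ValidationError, DegenerateInputError) as exc:
            logger.warning("skipping set %s: %s", name, exc)
            continue
        res.pathway = name
        results.append(res)
        logger.info(
            "pathway=%s n_genes=%d statistic=%.4g p=%.3g",
            name, res.n_genes_used, res.statistic, res.pvalue,
        )
    if not results:
        raise ValidationError("all gene sets were skipped")
    pvals = np.array([r.pvalue for r in results])
    adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    for r, a in zip(results, adj):
        r.pvalue_adj = float(a)
    results.sort(key=lambda r: (r.pvalue, r.pathway))
    return results
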