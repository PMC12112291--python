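"""Co-expression estimation from UMI counts under a Poisson measurement model.

The model: each cell i has a sequencing depth s_i and each gene j a latent
relative expression z_ij with mean mu_j, variance sigma_jj and pairwise
covariance sigma_jj'. Observed counts are x_ij | z_ij ~ Poisson(s_i z_ij).
The moment identities

    E(x_ij)                                = s_i mu_j
    Var(x_ij)                              = s_i mu_j + s_i^2 sigma_jj
    E[(x_ij - s_i mu_j)(x_ij' - s_i mu_j')] = s_i^2 sigma_jj'

are fit by three weighted least-squares regressions through the origin,
iterated (IRLS) with weights refreshed from the current (mu, sigma_diag):

1. mu_j:      regress x_ij on s_i,                weights 1 / v_ij
2. sigma_jj:  regress (x_ij - s_i mu_j)^2 - s_i mu_j on s_i^2, weights 1 / v_ij^2
3. sigma_jj': regress xi_ijj' = (x_ij - s_i mu_j)(x_ij' - s_i mu_j') on s_i^2,
              weights g_ijj' = 1 / (v_ij v_ij')

where v_ij = s_i mu_j + s_i^2 sigma_jj is the count variance. Under the null
of independent latent expression Var(xi_ijj') = v_ij v_ij', so the WLS slope
variance is 1 / sum_i g_ijj' s_i^4 and the standardised slope

    T_jj' = sigma_hat_jj' * sqrt(sum_i s_i^4 / (v_ij v_ij'))

is asymptotically N(0, 1), giving per-pair independence p-values.

Sequencing depth is taken as the per-cell total UMI count over all measured
genes, computed on the full matrix before any gene-set restriction so that
pathway-level results are mutually consistent. Multiplying all depths by a
constant rescales mu by 1/c and sigma by 1/c^2 but leaves correlations and
test statistics invariant, so no further depth normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ValidationError

__all__ = [
    "CscoreFit",
    "estimate_depths",
    "fit_cscore",
    "cscore_correlations",
    "coexpression_test",
]

_V_FLOOR = 1e-12  # floor on count variances when forming IRLS weights


@dataclass
class CscoreFit:
    """Moment estimates for a set of genes.

    Entries for degenerate genes (zero counts everywhere, or zero estimated
    overdispersion) are NaN in ``rho``/``tstat``/``pval`` — reported as
    missing, never as zero correlation.
    """

    genes: list[str]
    depths: np.ndarray          # (n,) per-cell s_i, strictly positive
    mu: np.ndarray              # (p,) per-gene relative expression >= 0
    sigma_diag: np.ndarray      # (p,) overdispersion variance, floored at 0
    sigma: np.ndarray           # (p, p) pairwise covariances, diag = sigma_diag
    rho: np.ndarray             # (p, p) correlations in [-1, 1], unit diagonal
    tstat: np.ndarray           # (p, p) independence test statistics
    pval: np.ndarray            # (p, p) two-sided normal p-values
    n_iter: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (gene_a, gene_b, r, T, p) over unordered pairs."""
        p = len(self.genes)
        ia, ib = np.triu_indices(p, k=1)
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in ia],
                "gene_b": [self.genes[i] for i in ib],
                "r": self.rho[ia, ib],
                "T": self.tstat[ia, ib],
                "p": self.pval[ia, ib],
            }
        )


def estimate_depths(cm: CountMatrix) -> np.ndarray:
    """Per-cell sequencing depth: total UMI count across all genes."""
    depths = cm.counts.sum(axis=1).astype(float)
    if np.any(depths <= 0):
        bad = [cm.cell_ids[i] for i in np.flatnonzero(depths <= 0)]
        raise ValidationError(f"cells with zero total count: {bad[:10]}")
    return depths


def _irls_moments(
    X: np.ndarray, s: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """IRLS for per-gene (mu, sigma_jj); X is (n, p) float, s is (n,)."""
    s2 = s * s
    s4 = s2 * s2
    mu = X.sum(axis=0) / s.sum()
    M = np.outer(s, mu)
    # initial sigma via unweighted regression of the variance residual on s^2
    sigma = np.maximum((s2 @ ((X - M) ** 2 - M)) / s4.sum(), 0.0)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        v = np.maximum(np.outer(s, mu) + np.outer(s2, sigma), _V_FLOOR)
        w = 1.0 / v
        mu_new = (s @ (w * X)) / (s2 @ w)
        M = np.outer(s, mu_new)
        y = (X - M) ** 2 - M
        h = w * w
        sigma_new = np.maximum((s2 @ (h * y)) / (s4 @ h), 0.0)
        delta = max(
            float(np.max(np.abs(mu_new - mu), initial=0.0)),
            float(np.max(np.abs(sigma_new - sigma), initial=0.0)),
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    return mu, sigma, n_iter, converged


def fit_cscore(
    cm: CountMatrix,
    genes: list[str] | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
    depths: np.ndarray | None = None,
) -> CscoreFit:
    """Fit the Poisson measurement model for ``genes`` (default: all).

    ``depths`` may be supplied to reuse depths computed on a larger matrix
    (e.g. before gene-set restriction); otherwise they are the per-cell
    totals over all genes in ``cm``.
    """
    if genes is None:
        genes = list(cm.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if depths is None:
        depths = estimate_depths(cm)
    else:
        depths = np.asarray(depths, dtype=float)
        if depths.shape != (cm.n_cells,):
            raise ValueError("depths length must match number of cells")
        if np.any(depths <= 0):
            raise ValidationError("depths must be strictly positive")
    idx = cm.gene_index(genes)
    X = cm.counts[:, idx].astype(float)
    return _fit_cscore_array(X, depths, genes, max_iter=max_iter, tol=tol)


def _fit_cscore_array(
    X: np.ndarray,
    s: np.ndarray,
    genes: list[str],
    max_iter: int = 10,
    tol: float = 1e-6,
) -> CscoreFit:
    """Core fit on a dense (n, p) count array with depths ``s``."""
    n, p = X.shape
    expressed = X.sum(axis=0) > 0  # all-zero genes get NaN everywhere

    mu = np.zeros(p)
    sigma_diag = np.zeros(p)
    n_iter, converged = 0, True
    if expressed.any():
        mu_e, sig_e, n_iter, converged = _irls_moments(
            X[:, expressed], s, max_iter, tol
        )
        mu[expressed] = mu_e
        sigma_diag[expressed] = sig_e

    # pairwise covariance slopes and their standard errors, vectorised:
    # with A_ij = s_i R_ij / v_ij and B_ij = s_i^2 / v_ij,
    # numerator  (A'A)_jj' = sum_i g s^2 xi   and
    # denominator(B'B)_jj' = sum_i g s^4, so slope = Num/Den, T = Num/sqrt(Den)
    s2 = s * s
    v = np.maximum(np.outer(s, mu) + np.outer(s2, sigma_diag), _V_FLOOR)
    R = X - np.outer(s, mu)
    A = (s[:, None] * R) / v
    B = s2[:, None] / v
    num = A.T @ A
    den = B.T @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = num / den
        tstat = num / np.sqrt(den)
    np.fill_diagonal(sigma, sigma_diag)

    defined = expressed & (sigma_diag > 0)
    sd = np.sqrt(np.where(defined, sigma_diag, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.clip(sigma / np.outer(sd, sd), -1.0, 1.0)
    np.fill_diagonal(rho, np.where(defined, 1.0, np.nan))

    undef = ~defined
    tstat[undef, :] = np.nan
    tstat[:, undef] = np.nan
    np.fill_diagonal(tstat, np.nan)
    pval = 2.0 * stats.norm.sf(np.abs(tstat))
    # guarantee p in (0, 1]: a huge |T| underflows the normal tail to 0
    tiny = np.nextafter(0.0, 1.0)
    pval = np.where(np.isnan(tstat), np.nan, np.maximum(pval, tiny))

    return CscoreFit(
        genes=list(genes),
        depths=s,
        mu=mu,
        sigma_diag=sigma_diag,
        sigma=sigma,
        rho=rho,
        tstat=tstat,
        pval=pval,
        n_iter=n_iter,
        converged=converged,
    )


def cscore_correlations(fit: CscoreFit) -> np.ndarray:
    """The estimated latent-expression correlation matrix (NaN = undefined)."""
    return fit.rho


def coexpression_test(fit: CscoreFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair independence test statistics and two-sided p-values."""
    return fit.tstat, fit.pval
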