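"""Synthetic scRNA-seq UMI counts with controllable co-expression structure.

The generator matches the estimator's own measurement model: per-gene latent
expression z_j follows a gamma marginal with mean mu_j and variance
sigma_jj = cv2_j * mu_j^2; a Gaussian copula imposes a block correlation
structure; per-cell depths s_i are lognormal; observed counts are
Poisson(s_i * z_ij).

Correlated genes are organised into compound-symmetric blocks (co-expression
modules) of varying size (``block_size_range``) and varying strength: each
block's copula correlation is drawn uniformly from ``block_corr`` +/-
``block_corr_spread``/2. Blocks are appended until the designated
within-block pair count reaches ``n_correlated_pairs``. On top of the
blocks, every gene loads equally on one global latent factor giving a weak
``background_corr`` between all gene pairs (within-block correlations are
adjusted so their total equals the block's target). This mirrors how
co-expression appears in real tissue: modules of unequal size and strength
— so genes differ in connectivity — embedded in pervasive weak co-expression
from shared cell state. Both features matter for eigenvector-weight
statistics: equal-degree, equal-strength structure perturbs all weights
symmetrically and leaves the scaled weight vector (hence the L1 statistic)
nearly unchanged, while a zero background makes any isolated correlated
pair stand out far more than it would in real data. Two matrices with identical marginals and depths are
produced: one preserving the copula correlations ("corr") and one with the
identity copula ("indep") — the correlation-destroying variant.

Pathways are assembled by drawing a number of designated correlated pairs
and topping up with uncorrelated genes; a pathway's truth label derives from
the fraction of its genes that belong to correlated pairs (positive if the
fraction exceeds ``positive_cutoff``, negative if below ``negative_cutoff``,
ambiguous otherwise).

Two corruption schemes emulate technical artefacts: dropout (preferentially
zeroing low counts until a target matrix-wide zero fraction is reached) and
multiplicative noise (random 30-50% inflation or 20-40% deflation of counts).

All randomness flows from ``SimulationSpec.seed`` through spawned
``numpy.random.SeedSequence`` substreams, so sub-results are independent and
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import CountMatrix, GeneSetCollection, ValidationError

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "build_pathways",
    "default_pathway_grid",
    "corrupt_dropout",
    "corrupt_noise",
]


@dataclass
class SimulationSpec:
    """Generating parameters for a paired (corr / indep) benchmark dataset.

    ``mu_range`` is sampled log-uniformly (relative expression spans orders
    of magnitude); ``disp_range`` is the range of the squared biological
    coefficient of variation, so sigma_jj = cv2 * mu_j^2.
    """

    n_genes: int = 500
    n_cells_per_condition: int = 3000
    mu_range: tuple[float, float] = (0.005, 0.05)
    disp_range: tuple[float, float] = (0.2, 1.0)
    depth_lognormal_params: tuple[float, float] = (np.log(400.0), 0.5)
    block_corr: float = 0.6
    block_corr_spread: float = 0.3
    block_size_range: tuple[int, int] = (2, 6)
    background_corr: float = 0.1
    n_correlated_pairs: int = 250
    pathway_sizes: list[int] = field(default_factory=lambda: [20, 40, 60, 80, 100])
    positive_cutoff: float = 0.4
    negative_cutoff: float = 0.2
    dropout_fraction: float = 0.0
    noise_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mu_range[0] <= self.mu_range[1]):
            raise ValueError("mu_range must be a positive nonempty interval")
        if not (0 <= self.disp_range[0] <= self.disp_range[1]):
            raise ValueError("disp_range must be a nonnegative nonempty interval")
        if not (0 < self.block_corr < 1):
            raise ValueError(
                "block_corr must lie in (0, 1); the pairwise copula blocks are "
                "positive definite only for |corr| < 1"
            )
        if self.block_corr + self.block_corr_spread / 2 >= 1 or (
            self.block_corr - self.block_corr_spread / 2 <= 0
        ):
            raise ValueError(
                "block_corr +/- block_corr_spread/2 must stay inside (0, 1)"
            )
        if self.negative_cutoff > self.positive_cutoff:
            raise ValueError("negative_cutoff must be <= positive_cutoff")
        if not (0 <= self.dropout_fraction <= 0.7):
            raise ValueError("dropout_fraction must be in [0, 0.7]")
        if not (0 <= self.noise_prob <= 0.7):
            raise ValueError("noise_prob must be in [0, 0.7]")
        if self.block_size_range[0] < 2 or self.block_size_range[0] > self.block_size_range[1]:
            raise ValueError("block_size_range must be an interval with lower bound >= 2")
        if not (0 <= self.background_corr < self.block_corr - self.block_corr_spread / 2):
            raise ValueError(
                "background_corr must be nonnegative and below the weakest "
                "block correlation"
            )
        hi = self.block_size_range[1]
        min_genes_needed = hi * int(np.ceil(self.n_correlated_pairs / (hi * (hi - 1) / 2)))
        if min_genes_needed > self.n_genes:
            # even all-maximal blocks (the most pair-efficient packing) overflow
            raise ValueError("not enough genes for the requested correlated pairs")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _gamma_marginal_ppf(u: np.ndarray, mu: np.ndarray, cv2: np.ndarray) -> np.ndarray:
    """Inverse-CDF of the gamma marginal with mean mu and variance cv2*mu^2."""
    shape = 1.0 / cv2
    scale = mu * cv2
    return stats.gamma.ppf(u, a=shape[None, :], scale=scale[None, :])


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[CountMatrix, CountMatrix, dict]:
    """Generate the paired correlation-preserving / -destroying matrices.

    Returns ``(cm_corr, cm_indep, truth)`` where ``truth`` records every
    generating parameter: per-gene ``mu`` and ``sigma_diag``, per-cell
    ``depths`` (shared by both matrices), the correlation ``blocks``
    (gene-ID lists with their copula correlation), the flattened designated
    ``correlated_pairs`` (gene-ID tuples) and their per-pair ``pair_rho``.
    """
    n, p = spec.n_cells_per_condition, spec.n_genes
    root = np.random.SeedSequence(spec.seed)
    ss_params, ss_depth, ss_pairs, ss_corr, ss_indep = root.spawn(5)

    rng_par = np.random.default_rng(ss_params)
    lo, hi = spec.mu_range
    mu = np.exp(rng_par.uniform(np.log(lo), np.log(hi), size=p))
    cv2 = rng_par.uniform(*spec.disp_range, size=p)
    cv2 = np.maximum(cv2, 1e-6)  # gamma shape must be finite
    sigma_diag = cv2 * mu**2

    meanlog, sdlog = spec.depth_lognormal_params
    depths = np.random.default_rng(ss_depth).lognormal(meanlog, sdlog, size=n)

    # partition random genes into compound-symmetric correlation blocks until
    # the designated within-block pair count reaches n_correlated_pairs
    rng_struct = np.random.default_rng(ss_pairs)
    shuffled = rng_struct.permutation(p)
    half = spec.block_corr_spread / 2
    lo_m, hi_m = spec.block_size_range
    blocks: list[tuple[np.ndarray, float]] = []
    pairs: list[tuple[int, int]] = []
    pair_rho_list: list[float] = []
    cursor = 0
    n_pairs = 0
    while n_pairs < spec.n_correlated_pairs:
        m = int(rng_struct.integers(lo_m, hi_m + 1))
        if cursor + m > p:
            raise ValueError(
                "ran out of genes while building correlation blocks; request "
                "fewer correlated pairs or smaller blocks"
            )
        rho_b = float(rng_struct.uniform(spec.block_corr - half, spec.block_corr + half))
        members = shuffled[cursor: cursor + m]
        cursor += m
        blocks.append((members, rho_b))
        for a_i in range(m):
            for b_i in range(a_i + 1, m):
                pairs.append((int(members[a_i]), int(members[b_i])))
                pair_rho_list.append(rho_b)
        n_pairs = len(pairs)
    pair_rho = np.array(pair_rho_list)

    bg = spec.background_corr

    def _draw(ss: np.random.SeedSequence, correlated: bool) -> np.ndarray:
        rng = np.random.default_rng(ss)
        y = rng.standard_normal((n, p))
        if correlated:
            for members, rho_b in blocks:
                # within-block residual correlation chosen so the total pair
                # correlation (background + block) equals rho_b exactly
                rho_resid = (rho_b - bg) / (1.0 - bg)
                shared = rng.standard_normal(n)
                y[:, members] = (
                    np.sqrt(rho_resid) * shared[:, None]
                    + np.sqrt(1.0 - rho_resid) * y[:, members]
                )
            if bg > 0:
                global_factor = rng.standard_normal(n)
                y = np.sqrt(bg) * global_factor[:, None] + np.sqrt(1.0 - bg) * y
        u = stats.norm.cdf(y)
        z = _gamma_marginal_ppf(u, mu, cv2)
        lam = depths[:, None] * z
        return rng.poisson(lam).astype(np.int64)

    x_corr = _draw(ss_corr, correlated=True)
    x_indep = _draw(ss_indep, correlated=False)

    gene_ids = [f"g{j:04d}" for j in range(p)]
    cm_corr = CountMatrix(
        x_corr, [f"corr_c{i:05d}" for i in range(n)], gene_ids
    )
    cm_indep = CountMatrix(
        x_indep, [f"indep_c{i:05d}" for i in range(n)], gene_ids
    )
    truth = {
        "mu": mu,
        "sigma_diag": sigma_diag,
        "cv2": cv2,
        "depths": depths,
        "block_corr": spec.block_corr,
        "background_corr": spec.background_corr,
        "pair_rho": pair_rho,
        "correlated_pairs": [(gene_ids[a], gene_ids[b]) for a, b in pairs],
        "blocks": [([gene_ids[g] for g in members], rho_b) for members, rho_b in blocks],
        "spec": spec.to_dict(),
    }
    return cm_corr, cm_indep, truth


def build_pathways(
    truth: dict,
    pathway_sizes: list[int],
    correlated_counts: list[int],
    all_genes: list[str],
    positive_cutoff: float = 0.4,
    negative_cutoff: float = 0.2,
    seed: int = 0,
) -> GeneSetCollection:
    """Assemble labeled pathways, one per (size, n_correlated_pairs) entry.

    ``pathway_sizes`` and ``correlated_counts`` are parallel lists: pathway k
    has ``pathway_sizes[k]`` genes of which ``2 * correlated_counts[k]`` are
    drawn from the correlation blocks (whole blocks first, then part of one
    more block if needed — a subset of a compound-symmetric block is itself
    fully co-expressed); the rest are uncorrelated fillers. The truth label
    follows from the achieved correlated-gene fraction.
    """
    if len(pathway_sizes) != len(correlated_counts):
        raise ValueError("pathway_sizes and correlated_counts must align")
    block_pool: list[list[str]] = [list(members) for members, _rho in truth["blocks"]]
    block_genes = {g for blk in block_pool for g in blk}
    filler_pool = [g for g in all_genes if g not in block_genes]
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    for k, (size, n_corr) in enumerate(zip(pathway_sizes, correlated_counts)):
        if 2 * n_corr > size:
            raise ValueError(
                f"pathway {k}: {n_corr} pairs ({2 * n_corr} genes) exceed size {size}"
            )
        if 2 * n_corr > len(block_genes):
            raise ValueError(
                f"pathway {k}: requested {2 * n_corr} correlated genes but only "
                f"{len(block_genes)} genes sit in correlation blocks"
            )
        order = rng.permutation(len(block_pool))
        genes: list[str] = []
        need = 2 * n_corr
        for b in order:
            if need <= 0:
                break
            blk = block_pool[b]
            if len(blk) <= need:
                genes.extend(blk)
                need -= len(blk)
            else:
                part = rng.choice(len(blk), size=need, replace=False)
                genes.extend(blk[i] for i in part)
                need = 0
        n_fill = size - len(genes)
        fill = rng.choice(len(filler_pool), size=n_fill, replace=False)
        genes += [filler_pool[f] for f in fill]
        frac = 2 * n_corr / size
        if frac > positive_cutoff:
            label = "positive"
        elif frac < negative_cutoff:
            label = "negative"
        else:
            label = "ambiguous"
        name = f"set{k:03d}_size{size}_pairs{n_corr}"
        sets[name] = genes
        labels[name] = label
    return GeneSetCollection(sets=sets, truth_label=labels)


def default_pathway_grid(
    pathway_sizes: list[int],
    positive_cutoff: float = 0.4,
    negative_cutoff: float = 0.2,
) -> tuple[list[int], list[int]]:
    """The benchmark grid: per size, correlated-pair counts spanning clearly
    negative (fractions 0, 0.1, 0.15) and clearly positive (0.5, 0.6, 0.8,
    1.0) content, floored/ceiled so achieved fractions stay on the intended
    side of the cutoffs. Returns parallel (sizes, counts) lists."""
    sizes: list[int] = []
    counts: list[int] = []
    for size in pathway_sizes:
        seen = set()
        for f in (0.0, 0.1, 0.15):
            n = int(np.floor(f * size / 2))
            if (2 * n / size) < negative_cutoff and n not in seen:
                seen.add(n)
                sizes.append(size)
                counts.append(n)
        for f in (0.5, 0.6, 0.8, 1.0):
            n = int(np.ceil(f * size / 2))
            if (2 * n / size) > positive_cutoff and n not in seen:
                seen.add(n)
                sizes.append(size)
                counts.append(n)
    return sizes, counts


def corrupt_dropout(
    cm: CountMatrix, target_zero_fraction: float, seed: int = 0
) -> CountMatrix:
    """Zero out low counts until the matrix-wide zero fraction hits the target.

    Nonzero entries are selected for zeroing with probability proportional to
    exp(-x) — low counts are preferentially dropped — via exact weighted
    sampling without replacement (Gumbel top-k). The achieved zero fraction
    equals the target to within one entry. Raises if the target is below the
    current zero fraction.
    """
    X = cm.counts
    total = X.size
    current = 1.0 - np.count_nonzero(X) / total
    if target_zero_fraction < current - 1e-12:
        raise ValidationError(
            f"target zero fraction {target_zero_fraction:.3f} below current "
            f"{current:.3f}"
        )
    k = int(round((target_zero_fraction - current) * total))
    if k == 0:
        return CountMatrix(X.copy(), list(cm.cell_ids), list(cm.gene_ids),
                           None if cm.condition is None else cm.condition.copy())
    flat_nz = np.flatnonzero(X)
    if k > len(flat_nz):
        raise ValidationError("target zero fraction exceeds what zeroing can reach")
    rng = np.random.default_rng(seed)
    logw = -X.reshape(-1)[flat_nz].astype(float)  # log weights: exp(-x)
    gumbel = rng.gumbel(size=len(flat_nz))
    drop = flat_nz[np.argpartition(-(logw + gumbel), k - 1)[:k]]
    out = X.copy().reshape(-1)
    out[drop] = 0
    return CountMatrix(out.reshape(X.shape), list(cm.cell_ids), list(cm.gene_ids),
                       None if cm.condition is None else cm.condition.copy())


def corrupt_noise(cm: CountMatrix, noise_prob: float, seed: int = 0) -> CountMatrix:
    """Multiplicative noise: each nonzero entry is independently selected with
    probability ``noise_prob`` and multiplied by Uniform(1.3, 1.5) (inflation)
    or Uniform(0.6, 0.8) (deflation), direction by fair coin, then rounded to
    the nearest integer. Zeros are untouched."""
    if not (0 <= noise_prob <= 0.7):
        raise ValueError("noise_prob must be in [0, 0.7]")
    X = cm.counts.copy()
    if noise_prob == 0:
        return CountMatrix(X, list(cm.cell_ids), list(cm.gene_ids),
                           None if cm.condition is None else cm.condition.copy())
    rng = np.random.default_rng(seed)
    flat = X.reshape(-1)
    nz = np.flatnonzero(flat)
    hit = nz[rng.random(len(nz)) < noise_prob]
    up = rng.random(len(hit)) < 0.5
    factor = np.where(
        up,
        rng.uniform(1.3, 1.5, size=len(hit)),
        rng.uniform(0.6, 0.8, size=len(hit)),
    )
    flat[hit] = np.rint(flat[hit] * factor).astype(X.dtype)
    return CountMatrix(X, list(cm.cell_ids), list(cm.gene_ids),
                       None if cm.condition is None else cm.condition.copy())
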