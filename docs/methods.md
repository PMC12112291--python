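# Methods

## The problem

Single-cell RNA-seq measures each cell's transcriptome as sparse UMI counts.
Within one cell type, the *co-expression* of two genes — the correlation of
their latent expression levels across cells — carries regulatory
information, and a change in the co-expression structure of a curated gene
set between two conditions (disease vs. healthy, treated vs. control) can
occur without any change in mean expression. Naive Pearson correlation of
counts is confounded by per-cell sequencing depth and attenuated by
count-level measurement noise, so this package estimates co-expression
under an explicit measurement model and tests gene sets for changes in
their network structure with a permutation test.

## Measurement model and moment estimation

For cell i and gene j, the latent relative expression z_ij has mean mu_j,
variance sigma_jj and pairwise covariance sigma_jj'; the observed count is

    x_ij | z_ij ~ Poisson(s_i z_ij),

with s_i the cell's sequencing depth, taken to be its total UMI count over
all measured genes (computed once on the full matrix, before any gene-set
restriction, so pathway results are mutually consistent). The moment
identities

    E(x_ij) = s_i mu_j
    Var(x_ij) = s_i mu_j + s_i^2 sigma_jj
    E[(x_ij - s_i mu_j)(x_ij' - s_i mu_j')] = s_i^2 sigma_jj'

are fit by three weighted least-squares regressions through the origin,
iterated (IRLS, default 10 iterations, tolerance 1e-6 on the maximum
absolute change of mu and sigma_diag) with weights refreshed from the
current estimates: the mean regression is weighted by 1/Var(x_ij), the
variance and covariance regressions by the squared inverse count variances.
Under the null of independent latent expression, the covariance slope
divided by its WLS standard error,

    T_jj' = sigma_hat_jj' * sqrt( sum_i s_i^4 / (v_ij v_ij') ),
    v_ij = s_i mu_j + s_i^2 sigma_jj,

is asymptotically N(0, 1), which the calibration test verifies by
Monte-Carlo (fraction of |T| > 1.96 close to 5% on independent genes at
2000 cells). Correlations are r_jj' = sigma_jj' / sqrt(sigma_jj sigma_j'j'),
clipped to [-1, 1].

Numerical choices: count variances are floored at 1e-12 when inverted into
weights; negative variance estimates are floored at 0 and the gene's
correlations reported as missing (NaN) rather than given an artificial
positive floor; genes with zero counts everywhere are likewise missing,
never "zero correlation". Multiplying all depths by a constant rescales mu
by 1/c and sigma by 1/c^2 but leaves r and T invariant (tested), so raw
depth totals are used without further normalisation.

## Gene-set network statistic

A gene set's network is summarised by per-gene weights solving
w_i = sum_{j != i} w_j |r_ij| — the leading (Perron) eigenvector of the
matrix of absolute correlations with zeroed diagonal. Absolute values make
the matrix entrywise nonnegative, guaranteeing a nonnegative, essentially
unique leading eigenvector; raw signed correlation matrices need not have
one. Weights are scaled to mean exactly 1 (w_norm = p w / sum w), the
simplest scaling putting values "around one"; all downstream quantities are
invariant to the scaling convention up to this documented contract. Genes
with any missing correlation are removed before the eigenvector step (at
least 3 must remain); a gene disconnected from the rest keeps weight 0.
If the two leading eigenvalues are within 1e-10 the set is flagged
`degenerate_spectrum` rather than silently perturbed.

The test statistic between conditions is the L1 distance between the two
scaled weight vectors. It is a *redistribution* statistic: it responds to
changes in the relative importance of genes, not to uniform shifts of all
correlations. The dispersion baseline (`gsca`) instead aggregates raw
changes: sqrt of the mean squared pairwise correlation difference.

## Permutation test

Cells are first balanced (the larger condition is downsampled without
replacement to the smaller one's size, deterministic given the seed; at
least 10 cells per condition required). The observed statistic uses the
true labels; the null is built by shuffling condition labels within the
balanced matrix (default 500 permutations; 200 in the benchmark). Each
pathway uses a seed derived as top-level seed + pathway index, so subsets
of a collection can be run separately and merged reproducibly.

Permutation statistics for the L1 statistic are close to normal (a
Shapiro-Wilk p-value is recorded per set as a diagnostic), so the default
p-value fits N(mean, sd) to the permutation sample and takes the upper
tail — one-sided, because the statistic is a nonnegative distance. An
empirical (k+1)/(n_perm+1) tail is available; if the permutation sample is
degenerate (sd = 0) the test falls back to it with a warning. Rankings are
computed from log-space tail probabilities (`norm.logsf`), which stay
defined when the normal tail underflows double precision. Benjamini-
Hochberg adjustment is applied across all sets of a scan.

Correlation backends: `gsncascr` fits the measurement model per condition
(depths from that condition's cells); `gsnca_pearson` and `gsca` use
Pearson correlation of depth-normalised (to the median depth),
log1p-transformed counts — the conventional normalisation pipeline. In the
benchmark the two baselines report empirical permutation p-values, matching
the convention of the original tools they model; their p-value floor ties
strongly differential pathways and visibly coarsens their rankings, which
is part of the behaviour being benchmarked. The modes are exposed as
arguments.

## Hub ranking

Weighted node connectivity (WNC) of gene i is the sum over partners of the
absolute correlation (condition networks) or absolute correlation
difference (differential network). Only the differential network is
thresholded (default |r1 - r2| > 0.2, strict); condition-network sums are
unthresholded, and the unthresholded differential sum is also reported.
Genes are ranked by thresholded differential WNC, ties broken by gene ID.
Missing correlations contribute 0.

## Synthetic data generator

The generator produces the paired study conditions: a correlation-
preserving and a correlation-destroying dataset with identical marginals
and identical per-cell depths. Latent expression follows gamma marginals
(mean mu_j, variance cv2_j mu_j^2) coupled by a Gaussian copula; observed
counts are Poisson(s_i z_ij). Defaults, chosen once to emulate a deeply
sequenced 10x-style panel of moderately-to-highly expressed genes:

| parameter | default | meaning |
|---|---|---|
| n_genes | 500 | panel size |
| n_cells_per_condition | 3000 | cells per condition (1500 in the desk-scale benchmark) |
| mu_range | (0.005, 0.05), log-uniform | relative expression |
| disp_range | (0.2, 1.0) | squared biological CV; sigma_jj = cv2 mu_j^2 |
| depth_lognormal_params | (log 400, 0.5) | per-cell depth s_i |
| block_corr, block_corr_spread | 0.6, 0.3 | per-block copula correlation ~ U(0.45, 0.75) |
| block_size_range | (2, 6) | co-expression module sizes |
| background_corr | 0.1 | weak global-factor correlation among all genes |
| n_correlated_pairs | 250 | designated within-block pairs |

These settings give a baseline zero fraction near 0.1 and mean counts of a
few per cell per gene. Correlated genes form compound-symmetric *blocks*
of varying size and strength rather than uniform disjoint pairs, embedded
in a weak equicorrelated background (one global latent factor, destroyed in
the independent condition like everything else; block correlations are
adjusted so each pair's total equals its target). Both features copy what
real co-expression looks like — modules with degree heterogeneity, hubs,
and pervasive weak correlation from shared cell state — and both matter
for an eigenvector statistic: perfectly symmetric equal-strength structure
leaves the scaled weight vector unchanged, and a zero background makes any
isolated pair spike unrealistically.

Pathways are assembled by drawing whole blocks (then part of one more
block; a subset of a compound-symmetric block is itself fully correlated)
until the requested number of correlated genes is reached, topped up with
uncorrelated fillers. The truth label derives from the correlated-gene
fraction: positive above 0.4, negative below 0.2, ambiguous between
(excluded from benchmark metrics). The benchmark grid uses sizes
20/40/60/80/100 with fractions {0, 0.1, 0.15} (negative) and
{0.5, 0.6, 0.8, 1.0} (positive), 34 labeled pathways.

Corruption schemes: *dropout* zeroes nonzero entries with probability
proportional to exp(-x) (low counts preferentially) via exact weighted
sampling without replacement until a target matrix-wide zero fraction is
reached; *multiplicative noise* selects nonzero entries independently with
a given probability and multiplies by U(1.3, 1.5) or U(0.6, 0.8) (fair
coin), rounding to the nearest integer. Cells left empty by corruption are
removed before testing (standard QC). All randomness flows from one seed
through spawned SeedSequence substreams.

What the generator does *not* emulate: real marginal count distributions
(it draws from smooth parametric families), batch effects, cell-type
mixtures, ambient RNA, or signed/negative co-expression. Because it
generates from the estimator's own model family, parameter-recovery tests
are a best case: passing them shows the estimator is correct under its
assumptions, not that those assumptions hold in any particular tissue.

## Benchmark and known limitations

The benchmark scans the labeled pathways in the combined
(preserving vs. destroying) matrix with all three methods, then scores
confusion metrics at BH-adjusted p < 0.05 (precision with zero calls is
reported as undefined, never 0 or 1) and a rank-based ROC AUC of the
-log10 p-values (Mann-Whitney probability, ties 1/2).

At the desk scale used by the test suite and the acceptance script
(500 genes, 1500 cells per condition, 34 pathways, 200 permutations,
3 replicate seeds), the signal in this generator is strong: every pathway
with destroyed correlated content is detected at a very large standardised
statistic. Two consequences are documented rather than hidden. First,
"negative" pathways with 10-15% correlated content are themselves truly
differential and are called significant, so sensitivity saturates at 1 and
the false-positive rate is substantial for all methods; separation between
methods shows up in the AUCs, where the measurement-model method
consistently outranks both Pearson baselines. Second, because the
eigenvector statistic saturates, moderate dropout corruption can *improve*
its ranking (by shrinking the statistic scale back into a discriminating
range) before information loss dominates at high dropout; AUC under
corruption is therefore not monotone in this regime, and the corresponding
monotonicity test fails and is left failing, with the mechanism recorded
here. A weak-signal regime in which all detection is borderline would
behave differently, but is not reachable with this generator's stated
correlation strengths and cell counts.

Other limitations: counts are held dense in memory (fine for ~10^3 x 10^3
desk scales; a sparse backend would be needed for full-transcriptome
atlases); exactly two conditions; no covariates or paired designs; gene
identifiers are matched by exact string equality.
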