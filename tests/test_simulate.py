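import numpy as np
import pytest
from scipy import stats

from diffcoexpr import (
    SimulationSpec,
    ValidationError,
    build_pathways,
    corrupt_dropout,
    corrupt_noise,
    default_pathway_grid,
    simulate_counts,
)


class TestSimulateCounts:
    def test_same_seed_bit_identical(self):
        spec = SimulationSpec(n_genes=50, n_cells_per_condition=100,
                              n_correlated_pairs=5, seed=3)
        a_corr, a_indep, _ = simulate_counts(spec)
        b_corr, b_indep, _ = simulate_counts(spec)
        assert np.array_equal(a_corr.counts, b_corr.counts)
        assert np.array_equal(a_indep.counts, b_indep.counts)

    def test_no_blocks_makes_conditions_exchangeable(self):
        """With zero correlated pairs the two matrices share one law."""
        spec = SimulationSpec(n_genes=200, n_cells_per_condition=1000,
                              n_correlated_pairs=0, seed=5)
        cm_corr, cm_indep, _ = simulate_counts(spec)
        ks = stats.ks_2samp(cm_corr.counts.mean(axis=0),
                            cm_indep.counts.mean(axis=0))
        assert ks.pvalue > 0.01

    def test_designated_pair_correlation_stands_out(self):
        """A 0.7-copula pair beats the 99th percentile of null pairs."""
        spec = SimulationSpec(
            n_genes=150, n_cells_per_condition=3000,
            block_corr=0.7, block_corr_spread=0.0, block_size_range=(2, 2),
            background_corr=0.0, n_correlated_pairs=1, seed=6,
        )
        cm_corr, _, truth = simulate_counts(spec)
        s = cm_corr.counts.sum(axis=1).astype(float)
        y = np.log1p(cm_corr.counts * (np.median(s) / s)[:, None])
        r = np.corrcoef(y, rowvar=False)
        (a, b), = truth["correlated_pairs"]
        ia, ib = cm_corr.gene_ids.index(a), cm_corr.gene_ids.index(b)
        iu = np.triu_indices(150, k=1)
        null = np.delete(r[iu], np.flatnonzero((iu[0] == ia) & (iu[1] == ib)))
        assert r[ia, ib] > 0
        assert r[ia, ib] > np.quantile(null, 0.99)

    def test_truth_records_blocks_and_pair_strengths(self, small_sim):
        spec, _, _, truth = small_sim
        assert len(truth["correlated_pairs"]) >= spec.n_correlated_pairs
        assert len(truth["pair_rho"]) == len(truth["correlated_pairs"])
        half = spec.block_corr_spread / 2
        assert np.all(truth["pair_rho"] >= spec.block_corr - half - 1e-12)
        assert np.all(truth["pair_rho"] <= spec.block_corr + half + 1e-12)
        block_sizes = [len(genes) for genes, _ in truth["blocks"]]
        assert min(block_sizes) >= spec.block_size_range[0]
        assert max(block_sizes) <= spec.block_size_range[1]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="block_corr"):
            SimulationSpec(block_corr=1.2)
        with pytest.raises(ValueError, match="not enough genes"):
            SimulationSpec(n_genes=20, n_correlated_pairs=50)
        with pytest.raises(ValueError, match="background_corr"):
            SimulationSpec(background_corr=0.5)


class TestBuildPathways:
    def test_truth_labels_follow_fraction_cutoffs(self, small_sim):
        spec, cm_corr, _, truth = small_sim
        col = build_pathways(truth, [10, 100, 20], [3, 0, 3],
                             list(cm_corr.gene_ids), seed=1)
        labels = [col.truth_label[n] for n in col.names()]
        # achieved fractions: 0.6 (positive), 0 (negative), 0.3 (ambiguous)
        assert labels == ["positive", "negative", "ambiguous"]
        for name, genes in col.sets.items():
            assert len(genes) == len(set(genes))

    def test_pathway_sizes_respected(self, small_sim):
        spec, cm_corr, _, truth = small_sim
        col = build_pathways(truth, [20, 40], [3, 6], list(cm_corr.gene_ids), seed=2)
        assert [len(g) for g in col.sets.values()] == [20, 40]

    def test_pairs_that_cannot_fit_rejected(self, small_sim):
        spec, cm_corr, _, truth = small_sim
        with pytest.raises(ValueError, match="exceed size"):
            build_pathways(truth, [10], [6], list(cm_corr.gene_ids), seed=0)

    def test_default_grid_spans_both_classes(self):
        sizes, counts = default_pathway_grid([20, 40, 60, 80, 100])
        assert len(sizes) >= 30
        fracs = [2 * n / s for s, n in zip(sizes, counts)]
        assert any(f < 0.2 for f in fracs) and any(f > 0.4 for f in fracs)
        assert all(f < 0.2 or f > 0.4 for f in fracs)


class TestCorruptDropout:
    def test_target_equal_to_current_is_identity(self, tiny_cm):
        cur = 1 - np.count_nonzero(tiny_cm.counts) / tiny_cm.counts.size
        out = corrupt_dropout(tiny_cm, cur, seed=0)
        assert np.array_equal(out.counts, tiny_cm.counts)

    def test_dense_matrix_reaches_target_fraction(self):
        rng = np.random.default_rng(1)
        from diffcoexpr import CountMatrix
        cm = CountMatrix(rng.poisson(8.0, size=(100, 100)) + 1,
                         [f"c{i}" for i in range(100)],
                         [f"g{j}" for j in range(100)])
        out = corrupt_dropout(cm, 0.7, seed=2)
        achieved = 1 - np.count_nonzero(out.counts) / out.counts.size
        assert 0.695 <= achieved <= 0.705
        # only zeroing happened
        changed = out.counts != cm.counts
        assert np.all(out.counts[changed] == 0)

    def test_low_counts_dropped_preferentially(self):
        """Entries at the matrix maximum are zeroed less often than ones."""
        from diffcoexpr import CountMatrix
        base = np.tile(np.array([[1, 10]]), (50, 1))
        cm = CountMatrix(base, [f"c{i}" for i in range(50)], ["lo", "hi"])
        lo_dropped = hi_dropped = 0
        for seed in range(200):
            out = corrupt_dropout(cm, 0.5, seed=seed)
            lo_dropped += int(np.sum(out.counts[:, 0] == 0))
            hi_dropped += int(np.sum(out.counts[:, 1] == 0))
        assert hi_dropped < lo_dropped

    def test_target_below_current_is_error(self, tiny_cm):
        with pytest.raises(ValidationError, match="below current"):
            corrupt_dropout(tiny_cm, 0.0, seed=0)


class TestCorruptNoise:
    def test_zero_probability_is_identity(self, tiny_cm):
        out = corrupt_noise(tiny_cm, 0.0, seed=0)
        assert np.array_equal(out.counts, tiny_cm.counts)

    def test_modified_entries_within_multiplicative_range(self):
        from diffcoexpr import CountMatrix
        rng = np.random.default_rng(3)
        base = rng.integers(1, 30, size=(50, 40))
        cm = CountMatrix(base, [f"c{i}" for i in range(50)],
                         [f"g{j}" for j in range(40)])
        out = corrupt_noise(cm, 0.7, seed=4)
        changed = np.flatnonzero(out.counts != cm.counts)
        v = cm.counts.reshape(-1)[changed].astype(float)
        m = out.counts.reshape(-1)[changed].astype(float)
        grid = np.concatenate([np.linspace(0.6, 0.8, 401),
                               np.linspace(1.3, 1.5, 401)])
        reachable = np.rint(v[:, None] * grid[None, :])
        assert np.all(np.any(reachable == m[:, None], axis=1))
        # zeros untouched
        assert np.all(out.counts[cm.counts == 0] == 0)

    def test_selection_fraction_concentrates(self):
        from diffcoexpr import CountMatrix
        base = np.full((400, 250), 3)
        cm = CountMatrix(base, [f"c{i}" for i in range(400)],
                         [f"g{j}" for j in range(250)])
        out = corrupt_noise(cm, 0.3, seed=5)
        frac = np.mean(out.counts != cm.counts)
        assert 0.29 <= frac <= 0.31
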