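import dataclasses

import numpy as np
import pytest

from diffcoexpr import (
    CountMatrix,
    GeneSetCollection,
    ValidationError,
    balance_cells,
    permutation_test,
    results_to_frame,
    run_pathway_scan,
)


def _two_condition_cm(rng, n_per=40, p=10, lam=4.0):
    # gamma-Poisson: overdispersed counts so the measurement-model
    # correlations are defined for every gene
    z = rng.gamma(shape=2.0, scale=lam / 2.0, size=(2 * n_per, p))
    counts = rng.poisson(z)
    cond = np.array(["x"] * n_per + ["y"] * n_per, dtype=object)
    return CountMatrix(counts, [f"c{i}" for i in range(2 * n_per)],
                       [f"g{j}" for j in range(p)], condition=cond)


class TestBalanceCells:
    def test_downsamples_larger_condition(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(180, 5))
        cond = np.array(["a"] * 100 + ["b"] * 80, dtype=object)
        cm = CountMatrix(counts, [f"c{i}" for i in range(180)],
                         [f"g{j}" for j in range(5)], condition=cond)
        bal = balance_cells(cm, seed=1)
        assert np.sum(bal.condition == "a") == np.sum(bal.condition == "b") == 80
        assert set(bal.cell_ids) <= set(cm.cell_ids)

    def test_equal_sizes_keep_all_cells(self, labeled_cm):
        bal = balance_cells(labeled_cm, seed=3)
        assert sorted(bal.cell_ids) == sorted(labeled_cm.cell_ids)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(150, 5))
        cond = np.array(["a"] * 90 + ["b"] * 60, dtype=object)
        cm = CountMatrix(counts, [f"c{i}" for i in range(150)],
                         [f"g{j}" for j in range(5)], condition=cond)
        assert balance_cells(cm, 7).cell_ids == balance_cells(cm, 7).cell_ids

    def test_too_few_cells_is_error(self):
        counts = np.ones((14, 4), dtype=int)
        cond = np.array(["a"] * 5 + ["b"] * 9, dtype=object)
        cm = CountMatrix(counts, [f"c{i}" for i in range(14)],
                         [f"g{j}" for j in range(4)], condition=cond)
        with pytest.raises(ValidationError, match="too few"):
            balance_cells(cm, 0)


class TestPermutationTest:
    @pytest.mark.parametrize("method", ["gsncascr", "gsnca_pearson", "gsca"])
    def test_duplicated_condition_gives_zero_statistic(self, method):
        """Two conditions made of the same cells give statistic exactly 0."""
        rng = np.random.default_rng(5)
        # overdispersed (gamma-Poisson) counts so latent variances are positive
        z = rng.gamma(shape=2.0, scale=2.0, size=(100, 8))
        block = rng.poisson(z)
        counts = np.vstack([block, block])
        cond = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        cm = CountMatrix(counts, [f"c{i}" for i in range(200)],
                         [f"g{j}" for j in range(8)], condition=cond)
        res = permutation_test(cm, list(cm.gene_ids), method=method,
                               n_perm=10, seed=0)
        assert res.statistic == 0.0

    def test_identical_seed_identical_result(self):
        rng = np.random.default_rng(6)
        cm = _two_condition_cm(rng)
        r1 = permutation_test(cm, list(cm.gene_ids), n_perm=20, seed=4)
        r2 = permutation_test(cm, list(cm.gene_ids), n_perm=20, seed=4)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(7)
        cm = _two_condition_cm(rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(cm, list(cm.gene_ids), n_perm=5, seed=0)

    def test_small_gene_set_rejected(self):
        rng = np.random.default_rng(8)
        cm = _two_condition_cm(rng)
        with pytest.raises(ValidationError, match=">= 3"):
            permutation_test(cm, ["g0", "g1", "not_measured"], n_perm=20, seed=0)

    def test_normal_and_empirical_pvalues_agree_when_null_is_normal(self):
        """With many permutations the two p-value modes nearly coincide."""
        rng = np.random.default_rng(9)
        cm = _two_condition_cm(rng, n_per=100, p=6)
        kwargs = dict(geneset=list(cm.gene_ids), method="gsnca_pearson",
                      n_perm=2000, seed=12)
        r_norm = permutation_test(cm, pvalue_mode="normal_approx", **kwargs)
        r_emp = permutation_test(cm, pvalue_mode="empirical", **kwargs)
        if r_norm.shapiro_p is not None and r_norm.shapiro_p > 0.05:
            assert abs(r_norm.pvalue - r_emp.pvalue) < 0.02


def _bh_oracle(pvals):
    """Textbook Benjamini-Hochberg with step-up monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestPathwayScan:
    def test_bh_oracle_reproduces_worked_example(self):
        np.testing.assert_allclose(_bh_oracle([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_scan_adjustment_matches_bh_oracle(self):
        rng = np.random.default_rng(10)
        cm = _two_condition_cm(rng, n_per=50, p=12)
        sets = GeneSetCollection(sets={
            "s1": ["g0", "g1", "g2", "g3"],
            "s2": ["g4", "g5", "g6"],
            "s3": ["g7", "g8", "g9", "g10", "g11"],
        })
        results = run_pathway_scan(cm, sets, method="gsca", n_perm=30, seed=2)
        raw = {r.pathway: r.pvalue for r in results}
        adj = _bh_oracle([raw[n] for n in sorted(raw)])
        got = {r.pathway: r.pvalue_adj for r in results}
        np.testing.assert_allclose([got[n] for n in sorted(raw)], adj, rtol=1e-12)
        assert all(r.pvalue_adj >= r.pvalue for r in results)

    def test_identical_seed_gives_identical_table(self):
        rng = np.random.default_rng(11)
        cm = _two_condition_cm(rng, n_per=40, p=8)
        sets = GeneSetCollection(sets={"a": ["g0", "g1", "g2"],
                                       "b": ["g3", "g4", "g5", "g6"]})
        f1 = results_to_frame(run_pathway_scan(cm, sets, method="gsca",
                                               n_perm=20, seed=5))
        f2 = results_to_frame(run_pathway_scan(cm, sets, method="gsca",
                                               n_perm=20, seed=5))
        assert f1.equals(f2)

    def test_undersized_set_skipped_but_logged(self, caplog):
        rng = np.random.default_rng(12)
        cm = _two_condition_cm(rng, n_per=40, p=8)
        sets = GeneSetCollection(sets={"ok": ["g0", "g1", "g2", "g3"],
                                       "tiny": ["g4", "nope1", "nope2"]})
        with caplog.at_level("WARNING", logger="diffcoexpr.testing"):
            results = run_pathway_scan(cm, sets, method="gsca", n_perm=20, seed=1)
        assert [r.pathway for r in results] == ["ok"]
        assert any("tiny" in rec.message for rec in caplog.records)

    def test_all_sets_skipped_is_error(self):
        rng = np.random.default_rng(13)
        cm = _two_condition_cm(rng, n_per=40, p=4)
        sets = GeneSetCollection(sets={"bad": ["zz1", "zz2", "zz3"]})
        with pytest.raises(ValidationError, match="skipped"):
            run_pathway_scan(cm, sets, method="gsca", n_perm=20, seed=1)

    def test_results_ordered_by_pvalue(self):
        rng = np.random.default_rng(14)
        cm = _two_condition_cm(rng, n_per=40, p=12)
        sets = GeneSetCollection(sets={
            f"s{k}": [f"g{3*k}", f"g{3*k+1}", f"g{3*k+2}"] for k in range(4)
        })
        results = run_pathway_scan(cm, sets, method="gsnca_pearson",
                                   n_perm=20, seed=3)
        pv = [r.pvalue for r in results]
        assert pv == sorted(pv)
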