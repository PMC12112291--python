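import numpy as np
import pytest

from diffcoexpr import CountMatrix, SimulationSpec, simulate_counts


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """2 cells x 3 genes with entries 0..5."""
    return CountMatrix(
        np.array([[0, 1, 2], [3, 4, 5]]),
        cell_ids=["c1", "c2"],
        gene_ids=["gA", "gB", "gC"],
    )


@pytest.fixture
def labeled_cm() -> CountMatrix:
    """A small two-condition matrix from a homogeneous population."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(60, 12))
    cond = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
    return CountMatrix(
        counts,
        cell_ids=[f"c{i}" for i in range(60)],
        gene_ids=[f"g{j}" for j in range(12)],
        condition=cond,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small paired simulation shared across tests (read-only)."""
    spec = SimulationSpec(
        n_genes=120,
        n_cells_per_condition=800,
        n_correlated_pairs=20,
        seed=7,
    )
    cm_corr, cm_indep, truth = simulate_counts(spec)
    return spec, cm_corr, cm_indep, truth
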