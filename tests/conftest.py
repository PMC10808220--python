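import numpy as np
import pytest

import anticorr as ac


@pytest.fixture(scope="session")
def small_null():
    """Small single-population NB dataset (300 genes x 150 cells)."""
    return ac.simulate_null_counts(n_cells=150, n_genes=300, seed=42)


@pytest.fixture(scope="session")
def two_block_data():
    """Planted 2-block matrix: two mutually exclusive 30-gene marker blocks
    plus 500 NB noise genes."""
    ds = ac.simulate_clustered_counts(
        n_clusters=2, n_cells=300, n_genes=560, n_deg=60,
        effect_size=10.0, seed=7,
    )
    return ds


@pytest.fixture(scope="session")
def four_cluster_nb():
    """Small 4-cluster NB dataset with log expression and selected features."""
    ds = ac.simulate_clustered_counts(
        n_clusters=4, n_cells=400, n_genes=800, n_deg=160,
        effect_size=10.0, seed=5,
    )
    expr = np.log2(1.0 + ds.counts)
    table = ac.get_anti_cor_genes(expr, cfg=ac.AnticorConfig(seed=5))
    return ds, expr, table["selected"].to_numpy()


@pytest.fixture(scope="session")
def four_blobs():
    """Four well-separated Gaussian blobs, 40 genes x 200 cells."""
    rng = np.random.default_rng(3)
    centers = rng.normal(0, 5, size=(4, 40))
    X = np.concatenate(
        [rng.normal(centers[c], 0.5, size=(50, 40)) for c in range(4)]
    )
    labels = np.repeat(np.arange(4), 50)
    return X.T, labels  # genes x cells
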