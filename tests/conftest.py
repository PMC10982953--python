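import numpy as np
import pytest

import spotdecon as sd


@pytest.fixture(scope="session")
def small_cfg():
    """Compact planted-marker configuration used across unit tests."""
    return sd.SyntheticConfig(n_types=4, n_cells=200, n_genes=400,
                              markers_per_type=20, marker_fold_change=10.0,
                              n_ref_spots=100, seed=123)


@pytest.fixture(scope="session")
def small_scrna(small_cfg):
    return sd.make_synthetic_scrna(small_cfg)


@pytest.fixture(scope="session")
def small_reference(small_cfg, small_scrna):
    return sd.make_synthetic_spatial_reference(small_cfg, small_scrna)


@pytest.fixture(scope="session")
def small_regular_sim(small_scrna):
    return sd.simulate_regular(small_scrna, 80, seed=5)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-epoch pipeline config for structural (non-recovery) tests."""
    return sd.RunConfig(seed=11, vae_epochs=40, gcn_epochs=150,
                        vae_hidden_dim=128)


@pytest.fixture
def toy_sc():
    """Hand-sized scRNA table: 6 cells, 2 types, 5 genes."""
    counts = np.array([
        [2, 0, 1, 0, 1],
        [3, 1, 0, 0, 2],
        [2, 1, 1, 0, 1],
        [0, 4, 0, 2, 0],
        [1, 3, 0, 3, 0],
        [0, 5, 1, 2, 0],
    ], dtype=float)
    return sd.SingleCellDataset(
        counts, ["A", "A", "A", "B", "B", "B"],
        [f"g{i}" for i in range(5)], [f"c{i}" for i in range(6)])
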