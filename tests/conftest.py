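import numpy as np
import pytest

from castle_sc import GeneExpressionDataset, SimulationConfig, simulate_pair


@pytest.fixture
def tiny_dataset():
    """4 cells x 3 genes, two classes, log-scale values."""
    m = np.array(
        [
            [0.0, 2.0, 7.0],
            [0.0, 1.5, 6.5],
            [3.0, 0.0, 0.5],
            [2.5, 0.0, 0.0],
        ]
    )
    return GeneExpressionDataset(
        m, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], ["T1", "T1", "T2", "T2"]
    )


@pytest.fixture(scope="session")
def small_pair():
    """A small but non-trivial simulated source/target pair (fast)."""
    cfg = SimulationConfig(
        n_genes=400,
        n_types=3,
        n_markers_per_type=10,
        cells_per_type_source=(80, 80, 80),
        cells_per_type_target=(60, 40, 20),
        seed=7,
    )
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def standard_pair():
    """The standard simulation fixture (full size; shared across tests)."""
    return simulate_pair(SimulationConfig(seed=0))
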