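import numpy as np
import pytest

from schurdle import SimulationSpec, attach_truth_et, simulate_dataset


@pytest.fixture(scope="session")
def small_table():
    """Small simulated dataset with ground-truth et/ngeneson attached."""
    spec = SimulationSpec(
        n_genes=10, cells_per_group=20, plates_per_batch=1, n_batches=1,
        cycle_effect_genes=(0,), cycle_effect_size=1.0, seed=42,
    )
    table, truth = simulate_dataset(spec)
    return attach_truth_et(table, truth), truth


@pytest.fixture(scope="session")
def null_pvalues():
    """Component and combined p-values for 1000 genes simulated with no
    cycle effect, 900 cells each (10 independent datasets of 100 genes)."""
    from schurdle import simulate_null, test_all_genes

    spec = SimulationSpec(
        n_genes=100, cells_per_group=100, plates_per_batch=1, n_batches=1, seed=0
    )
    frames = []
    for table, truth in simulate_null(spec, 10, seed=500):
        tt = attach_truth_et(table, truth)
        frames.append(test_all_genes(tt))
    import pandas as pd

    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
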