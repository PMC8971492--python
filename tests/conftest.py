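import numpy as np
import pandas as pd
import pytest

from cytobatch import CytometryDataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """2 batches x 1500 cells with moderate injected batch effects."""
    cfg = SimulationConfig(cells_per_batch=1500, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """2 batches x 1500 cells with zero injected batch effects."""
    cfg = SimulationConfig(
        cells_per_batch=1500, batch_shift_sd=0.0, batch_scale_sd=0.0, seed=12
    )
    return simulate_dataset(cfg)


def make_dataset(expression, batches, conditions=None, markers=None):
    """Build a CytometryDataset from bare arrays (test helper)."""
    expression = np.asarray(expression, dtype=float)
    n, m = expression.shape
    markers = markers or [f"M{j + 1:02d}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "sample_id": np.asarray(batches).astype(str),
            "batch_id": np.asarray(batches).astype(str),
            "condition": conditions if conditions is not None else [None] * n,
            "original_index": np.arange(n),
        }
    )
    return CytometryDataset(expression=expression, marker_names=markers, cell_meta=meta)
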