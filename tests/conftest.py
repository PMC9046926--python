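import numpy as np
import pandas as pd
import pytest

from degvenn import SimulationConfig, simulate_dataset
from degvenn.datatypes import CountMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Modest 2x2 dataset with shared signal, reused across read-only tests."""
    cfg = SimulationConfig(n_genes=600, n_per_cell=10, de_fraction=0.2, seed=12345)
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix: 6 genes x 8 samples, balanced 2x2."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    annotation = pd.DataFrame(
        {
            "group": ["G1"] * 4 + ["G2"] * 4,
            "condition": ["Ctrl", "Ctrl", "Treated", "Treated"] * 2,
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, annotation=annotation)
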