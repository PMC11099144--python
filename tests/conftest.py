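import numpy as np
import pandas as pd
import pytest

from togcn.expr_io import ExpressionMatrix, SampleSheet
from togcn.simulate import SimulationConfig, simulate_timecourse


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]],
        index=["gA", "gB"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def sheet_15() -> SampleSheet:
    rows = []
    for c in range(1, 6):
        for r in range(1, 4):
            rows.append((f"C{c}_R{r}", f"C{c}", c, str(r)))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "condition", "order", "replicate"]))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast synthetic dataset for IO/plumbing tests."""
    cfg = SimulationConfig(
        rng_seed=11,
        n_background_genes=40,
        n_scatter_tfs=40,
        n_housekeeping=30,
        tfs_per_wave=4,
        n_waves=5,
    )
    return simulate_timecourse(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
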