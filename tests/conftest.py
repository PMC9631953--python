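import numpy as np
import pandas as pd
import pytest

from sexscaff import (
    SimulationConfig,
    simulate_karyotype,
    simulate_depths,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def truth(default_config) -> pd.DataFrame:
    return simulate_karyotype(default_config)


@pytest.fixture(scope="session")
def depths(default_config, truth):
    return simulate_depths(truth, default_config)


def depth_table(ids, lengths, means) -> pd.DataFrame:
    """Hand-built DepthSummary table for small targeted cases."""
    return pd.DataFrame({
        "scaffold_id": list(ids),
        "length": np.asarray(lengths, dtype="int64"),
        "mean_depth": np.asarray(means, dtype=float),
    })
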