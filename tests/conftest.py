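import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pancistrome.synthio import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_sites=400, n_genes=60, seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """One modest synthetic panel shared across the suite."""
    return simulate_dataset(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
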