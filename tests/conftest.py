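import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radsub import SimConfig, simulate_population


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """The small reference simulation: 100 kb shared genome, 3 planted
    W regions, 4 + 4 individuals, error-free reads at mean depth 5."""
    return SimConfig(rng_seed=7)


@pytest.fixture(scope="session")
def population(sim_config):
    return simulate_population(sim_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
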