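from __future__ import annotations

import numpy as np
import pytest

from srnasig import simulate


@pytest.fixture(scope="session")
def standard_bundle():
    """One standard mixed-class simulated library shared across tests."""
    config = simulate.SimulationConfig(seed=11)
    library, truth, genome = simulate.simulate_library(config)
    return config, library, truth, genome


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
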