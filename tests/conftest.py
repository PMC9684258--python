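import numpy as np
import pytest

from microstates.montage import standard_1020_19
from microstates.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def montage():
    return standard_1020_19()


@pytest.fixture(scope="session")
def short_sim():
    """A 60 s default-condition simulation shared across tests."""
    cfg = SimulationConfig(duration=60.0, seed=11)
    return cfg, *simulate(cfg)


@pytest.fixture(scope="session")
def long_sim():
    """A 10 min default-condition simulation for convergence properties."""
    cfg = SimulationConfig(duration=600.0, seed=21)
    return cfg, *simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
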