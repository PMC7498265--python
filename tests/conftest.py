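import numpy as np
import pytest

from scsplice.sim_tech import SimulationConfig, TechParams, run_simulation


@pytest.fixture(scope="session")
def small_simulation():
    """A small mixed-regime simulation shared across read-only tests."""
    config = SimulationConfig(
        n_cells=60,
        n_per_regime={"bimodal": 40, "unimodal": 40, "included": 10, "excluded": 10},
        tech=TechParams(capture_mean=0.1),
        seed=123,
    )
    return run_simulation(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
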