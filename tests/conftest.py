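import numpy as np
import pytest

from pyrolith import SimulationConfig, make_rectangle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square7():
    return make_rectangle(7, 7)


@pytest.fixture
def base_config(square7):
    """Reference configuration: 7x7 surface, fully random placement, TB 0."""
    return SimulationConfig(
        grid=square7,
        n_occupations=30,
        fires_per_occupation=1,
        fire_size=1,
        scatters_per_occupation=4,
        lithics_per_scatter=100,
        tb_pct=0.0,
        introduced_pct=1.0,
        seed=7,
    )
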