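import numpy as np
import pytest

from regnomics import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        seed=7,
        n_genes=300,
        n_cells=300,
        n_clusters=4,
        isg_panel_size=24,
        isg_shift=0.5,
        n_deg=20,
        deg_fold=2.0,
    )


@pytest.fixture(scope="session")
def expression(small_config):
    return sd.simulate_expression(small_config)


@pytest.fixture(scope="session")
def regulatory(small_config):
    return sd.simulate_regulatory(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
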