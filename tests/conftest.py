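import numpy as np
import pytest

from chiralprop import (
    DEFAULT_FIELD,
    MOLECULE_I,
    MOLECULE_II,
    SimulationConfig,
    simulate,
)


@pytest.fixture(scope="session")
def molecule_i():
    return MOLECULE_I


@pytest.fixture(scope="session")
def molecule_ii():
    return MOLECULE_II


@pytest.fixture(scope="session")
def ref_field():
    return DEFAULT_FIELD


@pytest.fixture(scope="session")
def long_free_trajectory():
    """1e6-step free-diffusion run of molecule I, shared across estimator tests."""
    config = SimulationConfig(rotor=MOLECULE_I, field=None, dt=2e-12,
                              n_steps=1_000_000, record_every=1, seed=2024)
    return simulate(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
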