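import numpy as np
import pytest
from hypothesis import settings

import otem

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def masked_design():
    return otem.make_design("huang_masked")


@pytest.fixture(scope="session")
def unmasked_design():
    return otem.make_design("huang_unmasked")


@pytest.fixture(scope="session")
def demo_params():
    return otem.default_demo_params("otem_additive")


@pytest.fixture(scope="session")
def small_masked_dataset(masked_design, demo_params):
    """One simulated masked session (1600 trials, demo parameters)."""
    return otem.simulate_dataset(masked_design, demo_params, "otem_additive", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
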