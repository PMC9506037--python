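import numpy as np
import pytest

from cpaeos import Mixture, get_binary, get_component
from cpaeos.synthetic import NoiseSpec


@pytest.fixture(scope="session")
def co2():
    return get_component("CO2")


@pytest.fixture(scope="session")
def methanol():
    return get_component("methanol")


@pytest.fixture(scope="session")
def glycerol():
    return get_component("glycerol")


@pytest.fixture(scope="session")
def co2_methanol():
    return Mixture(["CO2", "methanol"], [get_binary("CO2", "methanol")])


@pytest.fixture(scope="session")
def co2_glycerol_one_site():
    return Mixture(["CO2", "glycerol"], [get_binary("CO2", "glycerol", variant="one_site")])


@pytest.fixture(scope="session")
def co2_peg200():
    return Mixture(["CO2", "PEG200"], [get_binary("CO2", "PEG200")])


@pytest.fixture(scope="session")
def srk_binary():
    """CO2 + methyl palmitate: no association anywhere (pure SRK limit)."""
    return Mixture(["CO2", "methyl_palmitate"], [get_binary("CO2", "methyl_palmitate")])


@pytest.fixture
def zero_noise():
    return NoiseSpec(sigma_P=0.0, sigma_y=0.0, sigma_v=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
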