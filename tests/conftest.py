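import numpy as np
import pytest

from biodeg.gas import BottleSpec
from biodeg.stoichiometry import parse_formula, potentials


@pytest.fixture
def pe():
    return parse_formula("C2H4")


@pytest.fixture
def pet():
    return parse_formula("C10H8O4")


@pytest.fixture
def pcl():
    return parse_formula("C6H10O2")


@pytest.fixture
def pcl_potentials(pcl):
    return potentials(pcl)


@pytest.fixture
def anaerobic_spec():
    return BottleSpec(
        total_volume_ml=120.0,
        liquid_volume_ml=45.0,
        temperature_c=55.0,
        initial_pressure_pa=1.7e5,
        initial_composition={"N2": 0.8, "CO2": 0.2},
    )


@pytest.fixture
def aerobic_spec():
    return BottleSpec(
        total_volume_ml=120.0,
        liquid_volume_ml=50.0,
        temperature_c=37.0,
        initial_pressure_pa=1.7e5,
        initial_composition={"N2": 0.7905, "O2": 0.2095},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
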