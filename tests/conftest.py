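import numpy as np
import pytest

from replibench.configio import build_lattice_config
from replibench.models import (
    StatePoint,
    builtin_forcefields,
    builtin_models,
)


@pytest.fixture(scope="session")
def models():
    return builtin_models()


@pytest.fixture(scope="session")
def forcefields():
    return builtin_forcefields()


@pytest.fixture(scope="session")
def water_toy_sp():
    """27 SPC/E waters in a small box with a correspondingly small cutoff."""
    return StatePoint("water-SPC/E", 27, 300.0, 101.325, 4.0)


@pytest.fixture(scope="session")
def water_toy(water_toy_sp):
    return build_lattice_config(water_toy_sp, seed=11)


@pytest.fixture(scope="session")
def methane_toy_sp():
    return StatePoint("methane-TraPPE", 64, 140.0, 1318.0, 7.0)


@pytest.fixture(scope="session")
def methane_toy(methane_toy_sp):
    return build_lattice_config(methane_toy_sp, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
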