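import numpy as np
import pytest

from mutsmith.energy import DEFAULT_PARAMETERIZATIONS, EnergyParams
from mutsmith.synthetic import toy_structure


@pytest.fixture(scope="session")
def helix8():
    return toy_structure("helix", n_residues=8)


@pytest.fixture(scope="session")
def dimer12():
    """Two-domain toy dimer with a 12 A cleft."""
    return toy_structure("two_domain_dimer", cleft=12.0, n_residues=8)


@pytest.fixture(scope="session")
def params_a() -> EnergyParams:
    return DEFAULT_PARAMETERIZATIONS[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
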