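import numpy as np
import pytest

from chemdepict.param_space import (
    FingerprintScheme,
    binary,
    categorical,
    register_decision,
    reference_profiles,
)
from chemdepict.rendering import parse_structure

CAFFEINE = "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"


@pytest.fixture(scope="session")
def caffeine_smiles():
    return CAFFEINE


@pytest.fixture(scope="session")
def caffeine(caffeine_smiles):
    return parse_structure(caffeine_smiles)


@pytest.fixture
def worked_example_scheme():
    """Binary kekulisation + categorical-3 bond width; 6 valid fingerprints."""
    scheme = FingerprintScheme((), "example")
    scheme = register_decision(scheme, binary("kekulised"))
    scheme = register_decision(
        scheme, categorical("bond_width", ["thin", "medium", "bold"])
    )
    return scheme


@pytest.fixture(scope="session")
def profiles():
    return reference_profiles()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
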