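import numpy as np
import pytest

from her6switch.adaptation import BasicModelParameters, SolverSettings
from her6switch.config import load_reference_config
from her6switch.extended import reference_extended_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_extended_parameters()


@pytest.fixture(scope="session")
def ref_basic(ref_params):
    return ref_params.basic


@pytest.fixture(scope="session")
def ref_cfg():
    return load_reference_config()


@pytest.fixture
def unit_basic():
    return BasicModelParameters(alpha_h=1.0, mu_h=1.0, alpha_X=1.0, mu_X=1.0)


@pytest.fixture(scope="session")
def fast_solver():
    """Looser tolerances for tests that only need qualitative outcomes."""
    return SolverSettings(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
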