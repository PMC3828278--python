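import os

import pytest
from hypothesis import HealthCheck, settings

from glosens import fixtures as fx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")
BIOMODELS_DIR = os.path.join(os.path.dirname(__file__), "biomodels")


@pytest.fixture(scope="session")
def chain():
    """Two-step irreversible chain (k1=2, k2=4, X0=1): J=2, S1*=0.5."""
    return fx.make_irreversible_chain()


@pytest.fixture(scope="session")
def reversible_chain():
    """Symmetric two-step reversible chain: flux control (0.5, 0.5)."""
    return fx.make_reversible_chain()


@pytest.fixture(scope="session")
def oscillator():
    """Harmonic centre with omega = pi: period exactly 2."""
    return fx.make_linear_oscillator()


@pytest.fixture(scope="session")
def bimodal_toy():
    return fx.make_bimodal_control_toy()


@pytest.fixture(scope="session")
def sbml_chain_path():
    return os.path.join(DATA_DIR, "two_step_chain.xml")
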