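import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netpaleo.phylogeny import Phylogeny
from netpaleo.synthetic import DEFAULT_KS, SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phylo() -> Phylogeny:
    return Phylogeny(branch_ks=dict(DEFAULT_KS))


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
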