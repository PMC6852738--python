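import numpy as np
import pytest

from apoptosim import synthetic
from apoptosim.model import KineticParameters, SimulationSettings


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def settings() -> SimulationSettings:
    return SimulationSettings()


@pytest.fixture(scope="session")
def fixture_bundle() -> dict:
    """Study-sized synthetic cohort bundle (n=46, 31 newly-diagnosed)."""
    return synthetic.make_fixture_cohort(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
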