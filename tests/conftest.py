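import numpy as np
import pytest

from palisade.fixtures import make_fixtures
from palisade.netgen import LatticeConfig, build_network


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_network(fixture_bundle):
    """Default-connectivity 10x10 network."""
    return fixture_bundle["network_10x10"]


@pytest.fixture(scope="session")
def tiny_network(fixture_bundle):
    """5x5 network with footprint half-length 2."""
    return fixture_bundle["network_5x5"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def network_20(request):
    return build_network(LatticeConfig(side_length=20, seed=7))
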