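import numpy as np
import pytest

from fhnsmr.model import ModelParams, SimControl
from fhnsmr.network import NetworkParams, build_ws_adjacency

#: the six-interval worked series used throughout the ordinal tests
WORKED_SERIES = np.array([1.1, 3.5, 2.3, 4.7, 1.8, 5.6])

#: FHN rest point for a=1.1 (solves x + a = 0 and x - x^3/3 - y = 0)
REST_X = -1.1
REST_Y = REST_X - REST_X**3 / 3.0


@pytest.fixture(scope="session")
def default_adjacency():
    """The reference operating-point network: N=100, k=30, p=0.15."""
    return build_ws_adjacency(NetworkParams(N=100, k=30, p=0.15, seed=1))


@pytest.fixture(scope="session")
def small_adjacency():
    """A small network for cheap integration tests."""
    return build_ws_adjacency(NetworkParams(N=20, k=4, p=0.1, seed=3))


@pytest.fixture
def worked_series():
    return WORKED_SERIES.copy()
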