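import numpy as np
import pytest

from actinwaves import Grid, build_actin_network, get_preset


@pytest.fixture(scope="session")
def fig4_params():
    return get_preset("fig4_standing")


@pytest.fixture(scope="session")
def fig11_params():
    return get_preset("fig11_travelling")


@pytest.fixture(scope="session")
def fig14_params():
    return get_preset("fig14_oscillatory")


@pytest.fixture(scope="session")
def fig4_network(fig4_params):
    return build_actin_network(fig4_params)


@pytest.fixture(scope="session")
def small_grid():
    return Grid(-5.0, 5.0, 100)


@pytest.fixture(scope="session")
def default_grid():
    return Grid()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
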