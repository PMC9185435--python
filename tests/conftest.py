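import numpy as np
import pytest

from jdenoise import NetSpec, build_network, make_synthetic_clean


SMALL_SPEC = NetSpec(donut_K=3, paths=((2, 2), (3, 2)), channels=8)


@pytest.fixture(scope="session")
def small_net():
    """A compliant randomly initialized net shared by read-only tests."""
    return build_network(SMALL_SPEC, seed=0)


@pytest.fixture(scope="session")
def baseline_net():
    return build_network(
        NetSpec(donut_K=3, paths=((2, 2), (3, 2)), channels=8,
                baseline_n2c=True), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shapes_image():
    return make_synthetic_clean("shapes", 64, 64, seed=3)
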