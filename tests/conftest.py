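import numpy as np
import pytest

from anchorq.fixtures import make_fixture


@pytest.fixture(scope="session")
def example1():
    return make_fixture("example1")


@pytest.fixture(scope="session")
def example2():
    return make_fixture("example2")


@pytest.fixture(scope="session")
def example3():
    return make_fixture("example3")


@pytest.fixture(scope="session")
def toy_noisy():
    return make_fixture("toy_noisy")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
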