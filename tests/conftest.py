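import numpy as np
import pytest

from remdsearch import make_fixture


@pytest.fixture(scope="session")
def minidrug():
    return make_fixture("minidrug", seed=0)


@pytest.fixture(scope="session")
def butane():
    return make_fixture("butane_like", seed=0)


@pytest.fixture(scope="session")
def double_well():
    return make_fixture("double_well_torsion", seed=0)


@pytest.fixture(scope="session")
def harmonic3d():
    return make_fixture("harmonic3d", seed=0)


@pytest.fixture(scope="session")
def water_box():
    return make_fixture("water_box", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
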