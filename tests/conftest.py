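import numpy as np
import pytest

from gridmapnav.environments import all_environments, test_locations


@pytest.fixture(scope="session")
def locset():
    return test_locations()


@pytest.fixture(scope="session")
def envs():
    return all_environments()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
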