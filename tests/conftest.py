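import numpy as np
import pytest

from mitoburden.region_map import load_region_map


@pytest.fixture(scope="session")
def region_map():
    return load_region_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
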