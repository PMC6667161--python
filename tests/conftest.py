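import warnings

import numpy as np
import pytest

import lcsim
from lcsim.synth import make_toy_country

# small-n runs warn about Monte Carlo noise; tests use them deliberately
warnings.filterwarnings("ignore", message="n_persons=.* is small")


@pytest.fixture(scope="session")
def china():
    return lcsim.load_country("china")


@pytest.fixture(scope="session")
def singapore():
    return lcsim.load_country("singapore")


@pytest.fixture(scope="session")
def all_countries():
    return {c: lcsim.load_country(c) for c in lcsim.COUNTRIES}


@pytest.fixture(scope="session")
def toy():
    """A toy country whose true parameters are stored in ``calibrated``."""
    return make_toy_country(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
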