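import warnings

import numpy as np
import pytest
from hypothesis import settings

from tibd import ModelParameters, make_recovery_benchmark, pre_equilibrate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def steady_state(params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pre_equilibrate(params)


@pytest.fixture(scope="session")
def benchmark():
    """Seeded nine-dataset synthetic study with known ground truth."""
    return make_recovery_benchmark(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
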