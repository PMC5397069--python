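import logging
import warnings

import numpy as np
import pytest

from betaox import (
    build_mfao_topology,
    find_steady_state,
    generate_linear_chain,
)
from betaox.mfao import substrate_parameter

logging.getLogger("betaox").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", message=".*roundoff error is detected.*")


@pytest.fixture(scope="session")
def mfao_model():
    """The curated full instance (do not mutate; copy first)."""
    return build_mfao_topology()


@pytest.fixture(scope="session")
def mfao_ss_low(mfao_model):
    """Converged steady state at 5 uM substrate (below the flux peak)."""
    model = mfao_model.copy()
    model.set_parameter(substrate_parameter(model), 5.0)
    res = find_steady_state(model)
    assert res.converged
    return model, res


@pytest.fixture(scope="session")
def mfao_ss_high(mfao_model):
    """Converged steady state at 60 uM substrate (past the flux peak)."""
    model = mfao_model.copy()
    model.set_parameter(substrate_parameter(model), 60.0)
    res = find_steady_state(model)
    assert res.converged
    return model, res


@pytest.fixture(scope="session")
def chain2():
    return generate_linear_chain(2)


@pytest.fixture(scope="session")
def chain3():
    return generate_linear_chain(3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
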