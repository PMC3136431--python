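import numpy as np
import pytest

import cyclewave as cw


@pytest.fixture(scope="session")
def params():
    return cw.default_params()


@pytest.fixture(scope="session")
def lc(params):
    """Wild-type limit-cycle summary, shared across the suite."""
    summary = cw.find_limit_cycle(params)
    assert summary.oscillatory
    return summary


@pytest.fixture(scope="session")
def arrest(params, lc):
    """CSF-arrested pre-fertilization steady state."""
    return cw.csf_arrested_state(params, lc)


@pytest.fixture(scope="session")
def prepared(lc, arrest):
    """(limit cycle, arrest array) pair in the form the solvers consume."""
    return lc, arrest.as_array()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
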