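import numpy as np
import pytest

from rhizoextent import load_parameters
from rhizoextent.scenarios import build_matrix, run_scenario


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def core_matrix_results(params):
    """All 12 core scenarios, run once per session (used by several tests)."""
    return [run_scenario(s) for s in build_matrix(params)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
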