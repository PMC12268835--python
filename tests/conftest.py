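import numpy as np
import pytest

from mimicslite import default_parameters, load_sites
from mimicslite.litterbag import run_design
from mimicslite.pipeline import daily_forcings_for


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def calibration_sites():
    return load_sites(role="calibration")


@pytest.fixture(scope="session")
def all_sites():
    return load_sites()


@pytest.fixture(scope="session")
def tree(calibration_sites):
    return next(s for s in calibration_sites if s.site_id == "TREE")


@pytest.fixture(scope="session")
def daily(calibration_sites):
    return daily_forcings_for(calibration_sites, seed=7)


@pytest.fixture(scope="session")
def default_design(calibration_sites, daily, params):
    """The 63-run historical design under default parameters (two timepoint
    rows per run)."""
    return run_design(calibration_sites, daily, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
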