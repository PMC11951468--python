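import numpy as np
import pytest

from ecmotwin.calibration import load_fixtures, load_params
from ecmotwin.calibration import cardio_from_params, hydraulics_from_params


@pytest.fixture(scope="session")
def fixtures():
    """Packaged bench fixture table."""
    return load_fixtures()


@pytest.fixture(scope="session")
def calibrated_params():
    """Packaged calibrated parameter set (fit once, shipped as YAML)."""
    return load_params()


@pytest.fixture(scope="session")
def cardio(calibrated_params):
    return cardio_from_params(calibrated_params)


@pytest.fixture(scope="session")
def hydraulics(calibrated_params):
    return hydraulics_from_params(calibrated_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
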