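import numpy as np
import pytest

from dmikit import AcquisitionParams, default_priors, make_atlas


@pytest.fixture(scope="session")
def acq():
    """Full-size acquisition: 10^3 grid, 700 points, 5 kHz."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq6():
    """Reduced 6^3 grid used by the end-to-end experiments."""
    return AcquisitionParams(matrix=(6, 6, 6))


@pytest.fixture(scope="session")
def priors(acq):
    return default_priors(acq)


@pytest.fixture(scope="session")
def atlas10():
    return make_atlas((10, 10, 10))


@pytest.fixture(scope="session")
def atlas6():
    return make_atlas((6, 6, 6))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
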