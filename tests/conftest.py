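import warnings

import pytest

from myoswarm import DEFAULT_CONSTANTS, DiscretizationWarning, get_isoform


@pytest.fixture(autouse=True)
def _quiet_discretization():
    # every run at an unloaded velocity has k_off*dT > 0.1 by construction;
    # the warning is informative for users, noise for the suite
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DiscretizationWarning)
        yield


@pytest.fixture(scope="session")
def consts():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def chicken():
    return get_isoform("chicken skeletal")


@pytest.fixture(scope="session")
def median():
    return get_isoform("median")


@pytest.fixture(scope="session")
def baseline():
    return get_isoform("baseline")
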