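import numpy as np
import pytest

from actcounts.filters import (
    default_modifiable_filter,
    discretize,
    frequency_response,
)


@pytest.fixture(scope="session")
def modifiable_analog():
    return default_modifiable_filter()


@pytest.fixture(scope="session")
def modifiable_30(modifiable_analog):
    return discretize(modifiable_analog, 30.0)


@pytest.fixture(scope="session")
def modifiable_100(modifiable_analog):
    return discretize(modifiable_analog, 100.0)


@pytest.fixture(scope="session")
def log_grid():
    return np.geomspace(0.05, 5.0, 200)


@pytest.fixture(scope="session")
def modifiable_reference(modifiable_analog, log_grid):
    """Magnitude table of the default modifiable filter, used as a fit target."""
    return frequency_response(modifiable_analog, log_grid)
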