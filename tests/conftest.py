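import numpy as np
import pytest

from hsrkinetics import (
    BASELINE,
    KineticParameters,
    ModelState,
    Protocol,
    integrate,
)


@pytest.fixture(scope="session")
def params():
    """Published nominal rate constants."""
    return KineticParameters()


@pytest.fixture(scope="session")
def init():
    """Published initial state at heat shock onset."""
    return ModelState()


@pytest.fixture(scope="session")
def grid_240():
    return np.arange(0.0, 240.5, 0.5)


@pytest.fixture(scope="session")
def baseline_traj(params, init, grid_240):
    """Sustained heat shock at the reference temperature, 0-240 min."""
    return integrate(params, init, Protocol.constant(BASELINE, 240.0), grid_240)
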