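import numpy as np
import pytest

from par3dyn import (
    FeedbackParameters,
    Grid1D,
    calibrate,
    simulate_maintenance,
)
from par3dyn.synthetic import make_initial_profile

#: dimensionless feedback strengths that locate the embryo in parameter space
EMBRYO_KF = 14.5
EMBRYO_KP = 62.0


@pytest.fixture(scope="session")
def embryo_fb():
    """Calibrated feedback parameters at the embryo point of the phase plane."""
    return calibrate(FeedbackParameters(K_f=EMBRYO_KF, K_P=EMBRYO_KP))


@pytest.fixture(scope="session")
def grid():
    return Grid1D()


@pytest.fixture(scope="session")
def polarized_init(embryo_fb, grid):
    return make_initial_profile("polarized", grid, K_P=embryo_fb.K_P,
                                amplitude=0.25, ratio=8.0)


@pytest.fixture(scope="session")
def control_run(embryo_fb, polarized_init):
    """Reference 240-s maintenance simulation, shared across tests."""
    return simulate_maintenance(polarized_init, embryo_fb, t_sim=240.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
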