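import numpy as np
import pytest

from colonywave.cascade import CascadeParams, simulate_cascade
from colonywave.fates import calibrate_rules
from colonywave.geometry import make_mask

# Canonical 700 um colony at 14 um/pixel (radius 25 px) on a 64-lattice:
# the control geometry shared across cascade and fate tests.


@pytest.fixture(scope="session")
def circle700():
    return make_mask("circle", 700.0, 64, 14.0)


@pytest.fixture(scope="session")
def small_mask():
    """Tiny circular mask for brute-force oracles."""
    return make_mask("circle", 8 * 14.0, 16, 14.0)


@pytest.fixture(scope="session")
def control_run(circle700):
    """Unperturbed cascade run on the 700 um circle (shared; read-only)."""
    return simulate_cascade(CascadeParams(), circle700)


@pytest.fixture(scope="session")
def fate_rules(control_run):
    """Fate rules calibrated once on the 700 um control circle."""
    return calibrate_rules(control_run)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
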