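import numpy as np
import pytest

from flexcat.potentials import double_well
from flexcat.pulsefit import PulseParams

#: parameters reported for the two-pulse working-memory fit
FITTED = PulseParams(k=0.012, alpha=0.70, sigma=0.52, tau_s=3.3)


@pytest.fixture(scope="session")
def fitted_params() -> PulseParams:
    return FITTED


@pytest.fixture
def tilted_well():
    return double_well(mu=0.15, alpha=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
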