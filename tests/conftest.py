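import numpy as np
import pytest

from capshell.mapping import PotentialParameters
from capshell.theory import ScaledParameters


@pytest.fixture(scope="session")
def belt_regime_params():
    """Conditions of the free-energy landscape comparison: small line
    tension, moderate drive, bending-dominated."""
    return ScaledParameters(lam=1e-4, dmu=1e-3, gamma=0.0)


@pytest.fixture(scope="session")
def cg_potential():
    """Coarse-grained potential of the lam = 0.00084 simulation series."""
    return PotentialParameters(m=24, n=12, nu=1.45, alpha=0.1)


class ZeroNoise:
    """Stands in for a Generator in zero-temperature (descent) integration."""

    def standard_normal(self, shape):
        return np.zeros(shape)


@pytest.fixture
def zero_noise():
    return ZeroNoise()
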