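import numpy as np
import pytest

from vesiquant import OpticalConfig, SizeDistribution


@pytest.fixture
def optical() -> OpticalConfig:
    """The default water/532 nm/90 deg configuration."""
    return OpticalConfig()


@pytest.fixture
def mono_dist() -> SizeDistribution:
    """Monodisperse decay-rate distribution at 0.0024 1/us (~89 nm)."""
    return SizeDistribution.monodisperse(0.0024)


@pytest.fixture
def bimodal_dist() -> SizeDistribution:
    """Two equal-intensity components with decay rates 10x apart."""
    return SizeDistribution(np.array([0.001, 0.01]), np.array([0.5, 0.5]))
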