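import numpy as np
import pytest

from mcflow import (
    ChannelSpec,
    Fluid,
    TissueBlock,
    TwoFluidDifferenceParams,
)


@pytest.fixture
def castor() -> Fluid:
    return Fluid(dynamic_viscosity=0.98, density=961.0)


@pytest.fixture
def olive() -> Fluid:
    return Fluid(dynamic_viscosity=0.08, density=911.0)


@pytest.fixture
def channel() -> ChannelSpec:
    """3 mm diameter, 32 mm long channel."""
    return ChannelSpec(radius=0.0015, length=0.032)


@pytest.fixture
def block() -> TissueBlock:
    """35 x 35 x 38 mm gelatin block at 7 kPa."""
    return TissueBlock(cross_section_area=0.035**2, x0=0.038, youngs_modulus=7000.0)


@pytest.fixture
def difference_params() -> TwoFluidDifferenceParams:
    """Castor-minus-olive difference parameters of the averaged fit."""
    return TwoFluidDifferenceParams(
        b1=1.16, tau1=8.1, b2=0.61, tau2=105.0, delta=42.37, ramp_duration=12.7
    )


@pytest.fixture
def hold_grid() -> np.ndarray:
    """10 Hz sampling over a 500 s relaxation test."""
    return np.arange(0.0, 500.0 + 1e-9, 0.1)
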