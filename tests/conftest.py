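import numpy as np
import pytest

from airtherm import DevicePlate, FluidProperties


@pytest.fixture
def air() -> FluidProperties:
    return FluidProperties(kappa=0.0257, rho_air=1.2, mu=1.8e-5, Pr=0.71)


@pytest.fixture
def plate() -> DevicePlate:
    return DevicePlate()


@pytest.fixture
def times() -> np.ndarray:
    return np.linspace(0.0, 10.0, 501)
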