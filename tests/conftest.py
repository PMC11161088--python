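import numpy as np
import pytest

from rosdyn import CompartmentState, DetachmentSchedule, ModelParameters, nondimensionalize


@pytest.fixture
def params():
    """Default (mouse/rat) parameter set."""
    return ModelParameters()


@pytest.fixture
def nd(params):
    return nondimensionalize(params)


@pytest.fixture
def normal():
    return DetachmentSchedule.normal()


@pytest.fixture
def adult_state(params):
    """Adult initial condition: (94, 627, 157) discs ≈ (3, 20, 5) μm."""
    return CompartmentState.from_discs(94, 627, 157, params.geometry)


@pytest.fixture
def single_disc(params):
    """Developing-rod initial condition: one nascent disc."""
    return CompartmentState.from_discs(1, 0, 0, params.geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
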