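import numpy as np
import pytest
from hypothesis import settings

from tfdimer import BindingModel, DimerKinetics, SelfAssociationModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def model():
    """Default self-association model: 48 kDa monomer, Kd 2 µM."""
    return SelfAssociationModel()


@pytest.fixture
def kinetics(model):
    """Dimer kinetics with kdiss 10 s⁻¹ (kass = 5 µM⁻¹s⁻¹ at Kd 2 µM)."""
    return DimerKinetics(kdiss=10.0, model=model)


@pytest.fixture
def binding():
    """Substrate-binding constants: monomer 0.5/6, dimer 1.1/30 (µM⁻¹s⁻¹, s⁻¹)."""
    return BindingModel()


@pytest.fixture
def t_grid():
    """Stopped-flow time grid: 2 ms dead time to 2 s."""
    return np.linspace(2e-3, 2.0, 800)
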