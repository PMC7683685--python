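import numpy as np
import pytest

from dynforce import BondModel, TrapConfig


@pytest.fixture
def trap_rigid():
    """Assay trap with a rigid linkage: true loading rate = apparent (5.6 pN/s)."""
    return TrapConfig(motor_stiffness=np.inf)


@pytest.fixture
def trap_compliant():
    """Default compliant linkage (0.2 pN/nm motor spring)."""
    return TrapConfig()


@pytest.fixture
def ideal_bond():
    """Force-independent bond; rupture forces are exponential with mean r/k0."""
    return BondModel.ideal(3.5)


@pytest.fixture
def slip_bond():
    return BondModel.slip(0.5, 1.0)
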