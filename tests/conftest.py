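import numpy as np
import pytest

from nmrelax.spin import CpmgDesign, DiffusionTensor, SpinSystem


@pytest.fixture(scope="session")
def spin800():
    return SpinSystem(800.2)


@pytest.fixture(scope="session")
def spin600():
    return SpinSystem(600.13)


@pytest.fixture(scope="session")
def design():
    """The standard two-field constant-time CPMG design."""
    return CpmgDesign()


@pytest.fixture(scope="session")
def iso_tensor():
    return DiffusionTensor("isotropic", 10.8e-9)


@pytest.fixture(scope="session")
def oblate_tensor():
    return DiffusionTensor("axial_oblate", 10.8e-9, 0.89)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
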