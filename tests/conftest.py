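import numpy as np
import pytest

from spsct.phantom import generate_phantom
from spsct.projector import forward_project, hu_to_mu


@pytest.fixture(scope="session")
def chest_phantom_128():
    """One fixed PE-positive chest phantom at 128x128."""
    return generate_phantom(seed=7, size=128, pe_present=True)


@pytest.fixture(scope="session")
def full_sino_128(chest_phantom_128):
    """2048-view parallel-beam acquisition of the fixed phantom."""
    return forward_project(hu_to_mu(chest_phantom_128.hu_image), 2048)


@pytest.fixture(scope="session")
def disk_64():
    """Uniform attenuation disk (mu units) on a 64x64 grid."""
    n = 64
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    img = np.zeros((n, n))
    img[(xx - c) ** 2 + (yy - c) ** 2 <= 20.0**2] = 0.02
    return img
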