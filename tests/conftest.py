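import numpy as np
import pytest

from astroquant import shearlet


@pytest.fixture(scope="session")
def system128():
    """Shared 3-scale shearlet system on a 128x128 grid."""
    return shearlet.build_system((128, 128), 3)


@pytest.fixture(scope="session")
def system256():
    return shearlet.build_system((256, 256), 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
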