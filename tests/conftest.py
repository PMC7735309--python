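import numpy as np
import pytest

from shearwf.phantoms import Ellipse
from shearwf.shearlets import ShearletConfig, build_shearlet_system


@pytest.fixture(scope="session")
def system64():
    """2-scale system on 64 x 64 (17 slices)."""
    return build_shearlet_system(ShearletConfig(64, n_scales=2))


@pytest.fixture(scope="session")
def system32():
    return build_shearlet_system(ShearletConfig(32, n_scales=1, shear_counts=(5,)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unit_disk():
    return [Ellipse(center=(0.0, 0.0), semi_axes=(0.5, 0.5), rotation=0.0, intensity=1.0)]
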