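import numpy as np
import pytest

from scalerd.geometry import (
    PrismLattice,
    build_gaussian_lattice,
    build_prism_lattice,
    extract_scale_map,
    voxelize,
)
from scalerd.models import KineticsSpec


@pytest.fixture(scope="session")
def prism_hf():
    """3x3 hexagonal-prism lattice, pitch 20, h_p/h = 0.3."""
    return build_prism_lattice(
        PrismLattice(n_x=3, n_y=3, scale_pitch=20.0, h=10.0, h_p=3.0, T=2.0, spacing=1.0, periodic=False)
    )


@pytest.fixture(scope="session")
def prism_sm(prism_hf):
    return extract_scale_map(prism_hf, 0.5)


@pytest.fixture(scope="session")
def prism_dom(prism_hf):
    return voxelize(prism_hf)


@pytest.fixture(scope="session")
def gaussian_hf():
    """Small Gaussian-bump lattice (3x3 scales)."""
    return build_gaussian_lattice(
        n_x=3, n_y=3, sigma=6.0, h=10.0, h_p=3.0, spacing=1.0, scale_pitch=20.0, periodic=False
    )


@pytest.fixture(scope="session")
def nakamasu():
    return KineticsSpec("nakamasu")


@pytest.fixture(scope="session")
def gray_scott():
    return KineticsSpec("gray_scott")


@pytest.fixture(scope="session")
def schnakenberg():
    return KineticsSpec("schnakenberg")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
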