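import numpy as np
import pytest

from bifex import (
    PhantomSpec,
    distance_map,
    extract_bifurcation,
    make_bifurcation_phantom,
    make_elliptical_tube_mask,
    make_tube_mask,
    minimal_cost_path,
)

ISO = (0.5, 0.5, 0.5)
CTA = (2.0, 0.5, 0.5)


@pytest.fixture(scope="session")
def straight_tube():
    """Straight cylinder r=3 mm, L=40 mm, isotropic 0.5 mm voxels."""
    mask, gt = make_tube_mask(3.0, 40.0, ISO)
    return mask, gt


@pytest.fixture(scope="session")
def straight_tube_centerline(straight_tube):
    mask, gt = straight_tube
    a, b = gt.markers["tube"]
    return minimal_cost_path(mask, a, b)


@pytest.fixture(scope="session")
def iso_phantom():
    """Default bifurcation (4, 2.68, 2.44 mm) at 0.5 mm isotropic voxels."""
    spec = PhantomSpec(spacing=ISO)
    mask, gt = make_bifurcation_phantom(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def iso_extraction(iso_phantom):
    spec, mask, gt = iso_phantom
    bc = extract_bifurcation(mask, gt.markers)
    return spec, mask, gt, bc, distance_map(mask)


@pytest.fixture(scope="session")
def cta_phantom():
    """Default bifurcation at CTA-like (2, 0.5, 0.5) mm voxels."""
    spec = PhantomSpec(spacing=CTA)
    mask, gt = make_bifurcation_phantom(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def elliptical_tube():
    """Straight tube with 3 x 2 mm elliptical cross-section."""
    mask, gt = make_elliptical_tube_mask(3.0, 2.0, 30.0, ISO)
    curve = minimal_cost_path(mask, [0.5, 0.0, 0.0], [29.5, 0.0, 0.0])
    return mask, gt, curve


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
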