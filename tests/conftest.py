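import numpy as np
import pytest

from tracheapat.forward import ArrayGeometry
from tracheapat.optics import ExtinctionTable
from tracheapat.recon import ReconImage


@pytest.fixture(scope="session")
def table():
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def fast_geometry():
    """Reduced element count for tests where full angular sampling is moot."""
    return ArrayGeometry(n_elements=48)


def render_annulus(inner_mm, outer_mm, spacing=0.05, n=256, value=1.0,
                   noise_sd=0.0, seed=0):
    """Ideal flat-top annulus image (analytic mask oracle for segmentation)."""
    axis = (np.arange(n) - (n - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(axis, axis)
    rho = np.hypot(xx, yy)
    img = np.where((rho > inner_mm) & (rho <= outer_mm), value, 0.0)
    if noise_sd > 0:
        img = np.abs(img + np.random.default_rng(seed).normal(0, noise_sd, img.shape))
    return ReconImage(pixels=img, spacing=spacing, origin=(axis[0], axis[0]))


@pytest.fixture
def annulus_image():
    return render_annulus(2.0, 3.0)
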