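import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from immunogradient import EPITHELIUM, STROMA, TissueMask


@pytest.fixture
def half_plane_mask():
    """Vertical straight interface: epithelium left, stroma right.

    200 x 200 px at 0.5 µm/px; boundary at x = 50 µm, length 100 µm.
    """
    labels = np.full((200, 200), STROMA, dtype=int)
    labels[:, :100] = EPITHELIUM
    return TissueMask(labels, pixel_size_um=0.5)


@pytest.fixture
def disk_mask():
    """Epithelium disk of radius 50 µm fully inside stroma (0.5 µm/px)."""
    n = 300  # 150 µm canvas
    yy, xx = np.mgrid[0:n, 0:n]
    labels = np.full((n, n), STROMA, dtype=int)
    r_px = 100  # 50 µm
    inside = ((yy + 0.5) - n / 2) ** 2 + ((xx + 0.5) - n / 2) ** 2 <= r_px**2
    labels[inside] = EPITHELIUM
    return TissueMask(labels, pixel_size_um=0.5)


def random_blob_mask(seed, size=96, smooth=8.0, pixel_size_um=1.0):
    """Random epithelium/stroma blob mask (thresholded smoothed noise)."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((size, size)), smooth)
    labels = np.where(f > 0, EPITHELIUM, STROMA)
    return TissueMask(labels, pixel_size_um=pixel_size_um)


@pytest.fixture
def blob_mask_factory():
    return random_blob_mask


def uniform_profile(density=100.0, max_rank=5, area=0.25):
    """Band density profile with identical density in every band."""
    from immunogradient import band_density_profile

    ranks = [r for r in range(-max_rank, max_rank + 1) if r != 0]
    counts = {r: int(round(density * area)) for r in ranks}
    areas = {r: area for r in ranks}
    return band_density_profile(counts, areas)


def profile_from_densities(densities: dict, area=1.0):
    """Profile with exactly the given per-rank densities (unit area)."""
    from immunogradient import band_density_profile

    counts = {r: int(round(d * area)) for r, d in densities.items()}
    areas = {r: area for r in densities}
    return band_density_profile(counts, areas)


@pytest.fixture
def profile_builder():
    return profile_from_densities


@pytest.fixture
def uniform_profile_builder():
    return uniform_profile
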