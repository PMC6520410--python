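import numpy as np
import pytest

from cortilam.model_io import CLayer, HierarchyLevel, ImageStack, LayerHierarchy


def hierarchy_from_levels(level_intervals, z_max, mc_start=None):
    """Build a LayerHierarchy from explicit per-level interval lists.

    ``level_intervals`` is a list (one entry per level, coarsening order)
    of lists of (z_start, z_end, cluster_id) triples.
    """
    if mc_start is None:
        mc_start = len(level_intervals)
    levels = []
    for li, intervals in enumerate(level_intervals):
        clayers = tuple(
            CLayer(s, e, cid, idx)
            for idx, (s, e, cid) in enumerate(intervals, start=1)
        )
        levels.append(HierarchyLevel(mc=mc_start - li, clayers=clayers))
    return LayerHierarchy(z_max=z_max, levels=levels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_stack():
    """Constant-intensity 3-slice stack."""
    return ImageStack(np.full((3, 32, 32), 10.0))


def gaussian_blob_stack(
    peak=200.0, background=20.0, sigma_px=3.0, size=64, n_slices=3, centre=None
):
    """Stack whose middle slice carries one Gaussian soma blob."""
    if centre is None:
        centre = (size // 2, size // 2)
    vox = np.full((n_slices, size, size), float(background))
    cy, cx = centre[1], centre[0]
    yy, xx = np.mgrid[0:size, 0:size]
    vox[n_slices // 2] += peak * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)
    )
    return ImageStack(vox, spacing=(1.0, 1.0, 2.0))
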