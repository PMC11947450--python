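import numpy as np
import pytest

from cloudband.gabor import ResponseGrid
from cloudband.geometry import DisplayGeometry

ORI_BINS = (-45.0, -22.5, 0.0, 22.5, 45.0)


@pytest.fixture
def small_geometry():
    """70 cm monitor at 17 cm, 640 px wide: ~0.2 deg/px."""
    return DisplayGeometry(70.0, 17.0, (640, 640))


def make_structured_grids(seed=0, n_sites=25, n_sfs=3, n_frames=4, patch_deg=30.0):
    """Narrow/broad response grids with orientation, SF and radial structure.

    The radial profile makes the surround mean depend on the annulus choice,
    so the suppression-model parameters are identifiable from these grids.
    """
    rng = np.random.default_rng(seed)
    c = (n_sites - 1) // 2
    idx = np.arange(n_sites) - c
    spacing = patch_deg / (n_sites - 1)
    rad = np.hypot(*np.meshgrid(idx, idx, indexing="ij")) * spacing
    sf_profile = np.linspace(0.6, 1.0, n_sfs)[None, :, None, None, None]
    grids = {}
    for j, cond in enumerate(("narrow", "broad")):
        ori_profile = np.exp(
            -0.5 * ((np.array(ORI_BINS) + 10 * j) / (20 + 25 * j)) ** 2
        )[:, None, None, None, None]
        spatial = (0.65 + 0.35 * np.cos(rad / 5.0))[None, None, None]
        m = 0.4 * ori_profile * sf_profile * spatial \
            * rng.uniform(0.5, 1.0, (5, n_sfs, n_frames, n_sites, n_sites))
        grids[cond] = ResponseGrid(
            m=m, orientations_deg=ORI_BINS, sfs_cpd=(0.01, 0.02, 0.04)[:n_sfs],
            spacing_deg=spacing, condition=cond,
        )
    return grids


@pytest.fixture
def structured_grids():
    return make_structured_grids()
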