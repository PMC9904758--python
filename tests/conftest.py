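import numpy as np
import pytest

from histoatlas import make_synthetic_atlas


@pytest.fixture
def box_atlas():
    """20^3 grid, one label-1 box spanning voxels [5, 15)^3, bregma at a corner."""
    spec = {
        "shape": (20, 20, 20),
        "voxel_size_mm": (0.05, 0.05, 0.05),
        "bregma_voxel": (0, 0, 0),
        "primitives": [{"kind": "box", "label": 1, "lo": (5, 5, 5), "hi": (15, 15, 15)}],
    }
    atlas, table = make_synthetic_atlas(spec, seed=0)
    return atlas, table


@pytest.fixture
def slab_atlas():
    """Stacked slabs at the brain surface: 0.3 mm (label 3) over 0.5 mm (label 2).

    Stacking is along DV; label 1 fills the rest of the brain box below.
    The brain surface sits at voxel z = 45.5, i.e. DV = -0.475 mm.
    """
    spec = {
        "shape": (60, 60, 60),
        "voxel_size_mm": (0.05, 0.05, 0.05),
        "bregma_voxel": (30, 30, 55),
        "primitives": [
            {"kind": "box", "label": 1, "lo": (5, 5, 5), "hi": (55, 55, 46)},
            # slab thicknesses: 10 voxels = 0.5 mm and 6 voxels = 0.3 mm
            {"kind": "box", "label": 2, "lo": (5, 5, 30), "hi": (55, 55, 40)},
            {"kind": "box", "label": 3, "lo": (5, 5, 40), "hi": (55, 55, 46)},
        ],
    }
    atlas, table = make_synthetic_atlas(spec, seed=0)
    return atlas, table


@pytest.fixture
def ellipsoid_atlas():
    """Brain ellipsoid with an inner labelled box, bregma near the top."""
    spec = {
        "shape": (40, 40, 40),
        "voxel_size_mm": (0.05, 0.05, 0.05),
        "bregma_voxel": (20, 20, 35),
        "primitives": [
            {"kind": "ellipsoid", "label": 1, "center": (20, 20, 20), "semi_axes": (17, 17, 15)},
            {"kind": "box", "label": 2, "lo": (10, 10, 10), "hi": (30, 30, 20)},
        ],
    }
    atlas, table = make_synthetic_atlas(spec, seed=1)
    return atlas, table


@pytest.fixture
def deep_atlas():
    """Rat-brain-scale volume (3.75 x 3.75 x 5.5 mm brain) for track fitting."""
    spec = {
        "shape": (80, 80, 120),
        "voxel_size_mm": (0.05, 0.05, 0.05),
        "bregma_voxel": (40, 40, 115),
        "primitives": [{"kind": "box", "label": 1, "lo": (5, 5, 5), "hi": (75, 75, 115)}],
    }
    atlas, table = make_synthetic_atlas(spec, seed=2)
    return atlas, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
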