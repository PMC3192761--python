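import numpy as np
import pytest

import histo3d as h

# one small, fully deterministic phantom shared by the whole suite:
# a depth-1 tree (trunk + 2 branches) plus one deliberately detached
# stained sphere, in a 120 x 120 x 80 um grid at 1 um voxels
PHANTOM_SPEC = dict(
    depth=1,
    detached_bodies=1,
    seed=3,
    segment_length_um=(20.0, 30.0),
    trunk_radius_um=8.0,
    wall_thickness_um=3.0,
)
PHANTOM_SHAPE_UM = (120.0, 120.0, 80.0)


@pytest.fixture(scope="session")
def phantom_grid():
    return h.generate_tube_tree(h.TubeTreeSpec(**PHANTOM_SPEC), shape_um=PHANTOM_SHAPE_UM)


@pytest.fixture(scope="session")
def clean_sections(phantom_grid):
    """Noise-free, perfectly aligned virtual sections + ground-truth masks."""
    stain = h.StainModel(noise_sigma=0.0, speck_rate=0.0)
    return h.virtual_sections(phantom_grid, thickness_um=5.0, stain=stain, seed=0)


@pytest.fixture(scope="session")
def noisy_sections(phantom_grid):
    stain = h.StainModel(noise_sigma=3.0, speck_rate=20.0)
    return h.virtual_sections(phantom_grid, thickness_um=5.0, stain=stain, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_section(rng):
    pixels = rng.integers(0, 256, size=(48, 64, 3)).astype(np.uint8)
    return h.SectionImage(pixels=pixels, pixel_size_um=1.0, section_index=0, thickness_um=5.0)
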