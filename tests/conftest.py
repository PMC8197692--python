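import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

import robustpet as rp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_level_volume(rng):
    """Factory: random integer-level volume + full mask."""

    def make(shape=(6, 6, 6), G=8, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        levels = r.integers(1, G + 1, size=shape).astype(np.int64)
        mask = np.ones(shape, dtype=bool)
        return levels, mask, G

    return make


@pytest.fixture(scope="session")
def blurred_sphere_pet():
    """Noise-free blurred homogeneous sphere, 10:1 contrast, d = 30 mm."""
    les = rp.homogeneous_sphere(15.0, 10.0)
    scene = rp.lesion_bed_scene(les, "sph")
    activity, truth, ct = rp.build_scene(scene, 1.0)
    pet = rp.apply_system(activity, rp.SystemModel(4.8, 2.0, 0.0, 0))
    mask2 = rp.block_downsample_mask(truth.masks["sph"], 2)
    return pet, truth, mask2


@pytest.fixture(scope="session")
def inward_hot_lesion_pet():
    """Noise-free blurred inward-hot multilayer lesion (hot core, cold rim)."""
    les = rp.multilayer_lesion("L4", (8.0, 4.0), 10.0)
    scene = rp.lesion_bed_scene(les, "l4")
    activity, truth, ct = rp.build_scene(scene, 1.0)
    pet = rp.apply_system(activity, rp.SystemModel(4.8, 2.0, 0.0, 0))
    mask2 = rp.block_downsample_mask(truth.masks["l4"], 2)
    return pet, truth, mask2
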