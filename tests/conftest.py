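import numpy as np
import pytest

from seedhsi.core import CalibrationSet, HyperspectralCube, SeedMask
from seedhsi.synth import SceneSpec, generate_seed_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """12 seeds on a 96x128 canvas, 16 bands — fast but fully featured."""
    return generate_seed_scene(
        SceneSpec(n_seeds=12, grid=(3, 4), image_size=(96, 128), n_bands=16, seed=42)
    )


@pytest.fixture
def flat_cube():
    """Uniform cube: every voxel 0.3, 5 bands at 500..900 nm."""
    wl = np.array([500.0, 600.0, 700.0, 800.0, 900.0])
    return HyperspectralCube(data=np.full((8, 10, 5), 0.3), wavelengths=wl)


@pytest.fixture
def three_ellipse_cube():
    """Three bright ellipses on a dark background, single-band friendly."""
    scene = generate_seed_scene(
        SceneSpec(n_seeds=3, grid=(1, 3), image_size=(40, 90), n_bands=6,
                  noise_sd=0.0, seed=7)
    )
    return scene
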