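import numpy as np
import pytest

import hsi_evoselect as h


@pytest.fixture(scope="session")
def small_scene():
    """One frame-like synthetic scene: 6 classes x 60 px, 128 bands."""
    spec = h.SceneSpec(height=24, width=24, pixels_per_class=60, n_classes=6)
    cube, labels = h.generate_scene(spec, seed=11)
    return spec, cube, labels


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down 7-image study (frame + comparison scenes)."""
    spec = h.SceneSpec(height=40, width=40, pixels_per_class=150, n_classes=6)
    return h.generate_study(spec, seed=7)


@pytest.fixture(scope="session")
def prepared_study(small_study):
    return h.prepare_dataset(small_study)


@pytest.fixture(scope="session")
def toy_pixels():
    """Well-separated 3-class pixel set, 30 bands, for optimiser tests."""
    return h.make_pixel_set(n_classes=3, n_per_class=40, n_bands=30, seed=5)


@pytest.fixture(scope="session")
def banded_pixels():
    """3 classes differing only on 10 informative bands of 60."""
    S = tuple(range(12, 52, 4))  # 10 bands spread over [12, 48]
    # noise high enough that accuracy keeps improving as more of S is
    # selected (no fitness saturation), so band selection has a gradient
    pix = h.make_pixel_set(n_classes=3, n_per_class=40, n_bands=60, seed=9,
                           informative_bands=S, noise_sigma=0.35)
    return S, pix


@pytest.fixture
def rng():
    return np.random.default_rng(0)
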