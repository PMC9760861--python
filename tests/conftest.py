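"""Shared fixtures: seeded synthetic scenes at the sizes the test suite
uses.  Scenes are generated once per session; tests must not mutate
them."""

import warnings

import numpy as np
import pytest

from dermseg import enhance
from dermseg.synthetic import SceneParams, generate_scene

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 256x256 scene: no hair, no bubbles, no illumination
    gradient; lesion gray 41-64, skin 157-181."""
    return generate_scene(SceneParams(
        size=(256, 256), n_hairs=0, n_bubbles=0, noise_sigma=0.0,
        illumination_amp=0.0, seed=1))


@pytest.fixture(scope="session")
def clean_scene_enhanced(clean_scene):
    lum = enhance.to_luminance(clean_scene.image)
    return enhance.adaptive_sigmoid(enhance.equalize_illumination(lum))


@pytest.fixture(scope="session")
def hairy_scene():
    """Default 256x256 scene with 10 hairs of thickness 2-3, no noise."""
    return generate_scene(SceneParams(
        size=(256, 256), n_hairs=10, hair_thickness_range=(2.0, 3.0),
        n_bubbles=0, noise_sigma=0.0, illumination_amp=0.0, seed=1))


@pytest.fixture(scope="session")
def small_scene():
    """Small, fast scene for plumbing tests."""
    return generate_scene(SceneParams(
        size=(96, 96), lesion_axes=(24.0, 19.0), n_hairs=3, n_bubbles=1,
        noise_sigma=0.0, illumination_amp=0.1, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def jaccard_of(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else float("nan")
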