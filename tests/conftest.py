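import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pollenvia import RgbImage, SyntheticSceneSpec, generate_scene

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: A small scene used by several unit tests: 26 grains on a 384x512 canvas.
SMALL_SPEC = SyntheticSceneSpec(
    image_size=(384, 512),
    n_viable=18,
    n_nonviable=8,
    n_artifacts=2,
    seed=42,
)


@pytest.fixture(scope="session")
def small_scene():
    """(image, truth) for the shared small synthetic scene."""
    return generate_scene(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_rgb(small_scene):
    img, _ = small_scene
    return RgbImage(pixels=img, source_id="small.png")


def viable_mask(truth, shape):
    """Boolean union of all viable-grain footprints (truth geometry)."""
    from skimage.draw import ellipse

    mask = np.zeros(shape, dtype=bool)
    for g in truth.grains:
        if g.viable:
            rr, cc = ellipse(*g.center, *g.axes, shape=shape, rotation=g.angle)
            mask[rr, cc] = True
    return mask


def nonviable_mask(truth, shape):
    from skimage.draw import ellipse

    mask = np.zeros(shape, dtype=bool)
    for g in truth.grains:
        if not g.viable:
            rr, cc = ellipse(*g.center, *g.axes, shape=shape, rotation=g.angle)
            mask[rr, cc] = True
    return mask
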