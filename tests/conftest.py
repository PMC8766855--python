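import logging

import numpy as np
import pytest

from vigncorr import GaussianSurfaceParams
from vigncorr.phantom import PhantomSpec, generate_phantom

logging.getLogger("vigncorr").setLevel(logging.WARNING)


def small_spec(**kw) -> PhantomSpec:
    """256x256 phantom spec with fields scaled to the smaller frame."""
    side = kw.pop("side", 256)
    c = (side - 1) / 2.0
    defaults = dict(
        width=side, height=side, n_slices=1, neurons_per_slice=60,
        true_brightness_field=GaussianSurfaceParams(60.0, c, c, 0.35 * side,
                                                    0.35 * side, 20.0),
        true_contrast_field=GaussianSurfaceParams(6.0, c, c, 0.4 * side,
                                                  0.4 * side, 3.0),
        seed=0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


def identity_spec(**kw) -> PhantomSpec:
    """Phantom with no vignetting: observed stack equals the true scene."""
    side = kw.pop("side", 256)
    c = (side - 1) / 2.0
    defaults = dict(
        width=side, height=side, n_slices=1, neurons_per_slice=60,
        # amplitude-0 surfaces: M_B == scene mean, M_C == scene std
        true_brightness_field=GaussianSurfaceParams(0.0, c, c, side, side,
                                                    100.0),
        true_contrast_field=GaussianSurfaceParams(0.0, c, c, side, side, 8.0),
        scene_background_mean=100.0, scene_background_std=8.0,
        seed=0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def phantom_256():
    """One vignetted 256x256 single-slice phantom, reused read-only."""
    return generate_phantom(small_spec(seed=11))


@pytest.fixture(scope="session")
def phantom_512():
    """Default-geometry 512x512 phantom (one slice), reused read-only."""
    return generate_phantom(PhantomSpec(n_slices=1, seed=7)), PhantomSpec(
        n_slices=1, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
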