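import numpy as np
import pytest

from ironage.simulate import (
    XanesSimConfig,
    XfmSimConfig,
    WormSpec,
    gen_xanes_stack,
    gen_xfm_scene,
)
from ironage.xanes import extract_normalized_spectrum


@pytest.fixture(scope="session")
def xanes_factory():
    """Factory for small uniform-fraction XANES stacks."""

    def make(f, shape=(12, 12), noise=True, seed=0, counts_scale=1e4,
             iron_density=1.0, jitter=0):
        # structured calcium blob so cross-correlation alignment has signal
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        ca = 0.2 + 2.0 * np.exp(
            -((yy - shape[0] / 3) ** 2 + (xx - shape[1] / 2) ** 2)
            / (2 * (shape[0] / 5) ** 2))
        cfg = XanesSimConfig(
            fe2_fraction_map=np.full(shape, f),
            iron_density_map=np.full(shape, iron_density),
            ca_density_map=ca,
            counts_scale=counts_scale,
            frame_jitter_px=jitter,
            poisson_noise=noise,
            seed=seed,
        )
        return gen_xanes_stack(cfg)

    return make


@pytest.fixture(scope="session")
def xanes_spec_factory(xanes_factory):
    """Factory for normalized ROI spectra from uniform stacks."""

    def make(f, **kwargs):
        stack, _ = xanes_factory(f, **kwargs)
        mask = np.ones(stack.frames.shape[1:], dtype=bool)
        return extract_normalized_spectrum(stack, mask)

    return make


@pytest.fixture(scope="session")
def two_worm_scene():
    """XFM scene with one whole-worm ROI (>10k px) and one fragment."""
    cfg = XfmSimConfig(
        scene_shape=(256, 360),
        worm_specs=[
            WormSpec(centroid=(100, 170), axes=(30, 130), orientation=0.2,
                     fe_density=0.02, ca_density=0.05),
            WormSpec(centroid=(210, 180), axes=(20, 85), orientation=0.0,
                     fe_density=0.03, ca_density=0.04),
        ],
        seed=4,
    )
    return gen_xfm_scene(cfg), cfg
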