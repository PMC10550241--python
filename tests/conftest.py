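import numpy as np
import pytest

from ptmtrack.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def confocal_scene():
    """Rendered confocal-scale scene shared by segmentation tests."""
    cfg = SceneConfig(seed=7, n_frames=6, pixel_size=0.096, n_tracks=50,
                      image_shape=(256, 256), n_regions=40)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def spt_scene():
    """Statistics-only scene at single-molecule imaging scale."""
    cfg = SceneConfig(seed=3, n_tracks=400)
    return generate_scene(cfg, render_images=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
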