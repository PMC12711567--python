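import numpy as np
import pytest

from mammostroma.pericell import MultiplexImage
from mammostroma.synth import SceneSpec, gen_multiplex_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless scene: enrichment factor 2.0 over baseline 0.2."""
    spec = SceneSpec(seed=11, noise_sd=0.0, n_cells_per_class=(6, 6))
    return gen_multiplex_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    spec = SceneSpec(seed=12, noise_sd=0.02)
    return gen_multiplex_scene(spec)


def as_image(scene) -> MultiplexImage:
    return MultiplexImage(scene.channels, scene.channel_names,
                          scene.pixel_size_um)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
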