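import numpy as np
import pytest

from lysopos import pipeline, synthetic


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale scene parameters used across the suite."""
    return synthetic.SceneParams.small(seed=11)


@pytest.fixture(scope="session")
def noisefree_params():
    return synthetic.SceneParams(
        image_size=(256, 256),
        cell_radius_mean=80.0,
        cell_radius_jitter=5.0,
        n_puncta=50,
        min_separation=7.0,
        shot_noise=False,
        gaussian_read_noise_sd=0.0,
        seed=21,
    )


@pytest.fixture(scope="session")
def default_scene(small_params):
    """One noisy scene plus its ground truth (shared, read-only)."""
    return synthetic.generate_cell_scene(small_params)


@pytest.fixture(scope="session")
def default_segmentation(default_scene):
    scene, _ = default_scene
    return pipeline.segment_scene(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
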