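import pytest

from costripe import COSceneParams
from costripe.pipeline import segment_scene
from costripe.synthetic import generate_co_map


@pytest.fixture(scope="session")
def noisy_scene():
    """A realistic jittered-lattice CO scene with shading and noise."""
    params = COSceneParams(seed=11, shading_amplitude=0.15, noise_sd=0.02)
    co, truth = generate_co_map(params)
    return params, co, truth


@pytest.fixture(scope="session")
def clean_scene():
    """A noise- and shading-free scene (exact geometry checks)."""
    params = COSceneParams(seed=7, shading_amplitude=0.0, noise_sd=0.0)
    co, truth = generate_co_map(params)
    return params, co, truth


@pytest.fixture(scope="session")
def segmented_scene(noisy_scene):
    """The standard segmentation chain applied to the noisy scene."""
    params, co, truth = noisy_scene
    blobs = segment_scene(co, params.blob_spacing_um, params.blob_diameter_um)
    return params, co, truth, blobs
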