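import numpy as np
import pytest

from fluoroscan import (
    ImagingModel,
    PlantMask,
    SceneSpec,
    build_scene,
    render_stack,
)


@pytest.fixture(scope="session")
def default_spec():
    return SceneSpec()


@pytest.fixture(scope="session")
def small_spec():
    # Quarter-scale bed position: fast, still multiple plants/leaves.
    return SceneSpec(image_height=180, image_width=240, n_plants=2, leaves_per_plant=5)


@pytest.fixture(scope="session")
def healthy_field(small_spec):
    return build_scene(small_spec, seed=11)


@pytest.fixture(scope="session")
def full_field(default_spec):
    return build_scene(default_spec, seed=42)


@pytest.fixture(scope="session")
def noiseless_imaging():
    return ImagingModel(read_noise_sd=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def default_imaging():
    return ImagingModel()


@pytest.fixture(scope="session")
def noiseless_stack(healthy_field, noiseless_imaging):
    return render_stack(healthy_field, noiseless_imaging, seed=0)


@pytest.fixture(scope="session")
def noisy_stack(healthy_field, default_imaging):
    return render_stack(healthy_field, default_imaging, seed=42)


@pytest.fixture
def footprint_mask(healthy_field):
    return PlantMask(mask=healthy_field.footprint, provenance="fluorescence_threshold")


def quantize_stack(stack):
    """Round a noiseless stack's counts so it is TIFF-writable."""
    for k in stack.frames:
        stack.frames[k] = np.round(stack.frames[k])
    return stack
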