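import numpy as np
import pytest

from lesionseg import fixtures as fx
from lesionseg import models


@pytest.fixture(scope="session")
def small_spec() -> fx.SynthSpec:
    """64x64 rendering spec used throughout the unit tests."""
    return fx.SynthSpec(image_size=(64, 64))


@pytest.fixture(scope="session")
def hairy_spec() -> fx.SynthSpec:
    """128x128 spec that always carries hair strokes."""
    return fx.SynthSpec(image_size=(128, 128), hair_count_range=(3, 8))


@pytest.fixture(scope="session")
def sample(small_spec) -> fx.LesionSample:
    return fx.generate_lesion_sample(small_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_models():
    """One tiny instance of each architecture (32x32 input, width 4)."""
    return {arch: models.build_model(
        models.ModelConfig(arch=arch, input_size=32, base_width=4, seed=0))
        for arch in ("unet", "resunet", "resunetpp")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
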