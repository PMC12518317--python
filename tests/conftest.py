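import numpy as np
import pytest
from hypothesis import settings

from cnatnet.synth import DatasetConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ds_small(tmp_path_factory):
    """Small fast dataset (60 images at 96 px) for integration checks."""
    out = tmp_path_factory.mktemp("ds_small")
    return generate_dataset(DatasetConfig(out_dir=out, n_images=60,
                                          image_size=96, seed=7))


@pytest.fixture(scope="session")
def ds_desk(tmp_path_factory):
    """Default-size dataset rendered at the 64-px desk training resolution."""
    out = tmp_path_factory.mktemp("ds_desk")
    return generate_dataset(DatasetConfig(out_dir=out, image_size=64, seed=1))


@pytest.fixture(scope="session")
def ds_localized(tmp_path_factory):
    """Desk-resolution dataset whose grade cue is carried by localized
    colour spots along each filament rather than the whole-stroke colour."""
    out = tmp_path_factory.mktemp("ds_loc")
    return generate_dataset(DatasetConfig(out_dir=out, image_size=64,
                                          seed=11, cue="localized"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
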