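import numpy as np
import pytest

from cowseg.data_io import split_dataset
from cowseg.synthetic_scenes import SceneParams, generate_dataset


@pytest.fixture(scope="session")
def desk_scene_params():
    return SceneParams(image_size=(96, 160), clutter_level=0.5, seed=7)


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory, desk_scene_params):
    """A small paired dataset shared across tests (24 animals, 96x160)."""
    out = tmp_path_factory.mktemp("mini_data")
    manifest = generate_dataset(desk_scene_params, 24, out)
    return manifest


@pytest.fixture(scope="session")
def mini_split(mini_dataset):
    return split_dataset(mini_dataset, (0.8, 0.2), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
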