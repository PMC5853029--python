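import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from focusqc import (ModelSpec, OpticalParams, SceneSpec, SensorModel,
                     TrainConfig, make_dataset, train)


@pytest.fixture(scope="session")
def optical_params():
    return OpticalParams()


@pytest.fixture(scope="session")
def sensor():
    return SensorModel(offset=100.0, gain=2.0)


@pytest.fixture(scope="session")
def small_scene_spec():
    """A compact scene, just big enough for a 2x2 patch grid."""
    return SceneSpec(height=168, width=168, blob_count_range=(6, 12),
                     foreground_fraction_target=0.05)


@pytest.fixture(scope="session")
def small_dataset(small_scene_spec, optical_params, sensor):
    """Two-scene train/test patch sets for fast end-to-end checks."""
    return make_dataset(2, small_scene_spec, optical_params, sensor,
                        patches_per_image=4, seed=11)


@pytest.fixture(scope="session")
def mini_model(small_dataset):
    """A briefly trained model: enough steps for sanity, not accuracy."""
    train_set, _ = small_dataset
    cfg = TrainConfig(steps=150, batch_size=8, learning_rate=1e-3, seed=3)
    return train(train_set, ModelSpec(), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
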