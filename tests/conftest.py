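import numpy as np
import pytest

from earcount.model import TrainConfig, fit_model
from earcount.synthetic_data import SceneConfig, generate_scene

SMALL_SCENE = dict(height=200, width=260, ear_count=5, min_separation=55,
                   ear_axis_range=(10.0, 14.0))


@pytest.fixture(scope="session")
def small_scenes():
    """Three small labeled scenes, one per illumination level."""
    return [
        generate_scene(SceneConfig(seed=40 + i, illumination=ill, **SMALL_SCENE))
        for i, ill in enumerate(("low", "medium", "high"))
    ]


@pytest.fixture(scope="session")
def tiny_model(small_scenes):
    """A quickly trained model for pipeline-level tests (not for accuracy)."""
    return fit_model(
        small_scenes,
        train_config=TrainConfig(max_per_class=200, mining_rounds=1, seed=0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_patches(rng):
    """Five random 8-bit RGB patches for oracle comparisons."""
    return [rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8) for _ in range(5)]
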