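import numpy as np
import pytest

from moequant.synth import SceneParams


@pytest.fixture
def small_scene_params():
    """Compact scene used where geometry, not scale, is under test."""
    return SceneParams(
        shape=(256, 256),
        n_cells=4,
        cell_radius_px=(22.0, 30.0),
        f_golgi=0.6,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
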