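import numpy as np
import pytest

from camoevolve.scene_synth import habitat_library, make_scene_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene_pair():
    """One reduced-size habitat rendered under both lightings."""
    hp = habitat_library(10)[7]  # gravel, mid 3-D amplitude
    direct = make_scene_set(hp, "DIRECT", n_scenes=1, size=(288, 352),
                            target_diameter=40)[0]
    diffuse = make_scene_set(hp, "DIFFUSE", n_scenes=1, size=(288, 352),
                             target_diameter=40)[0]
    return direct, diffuse
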