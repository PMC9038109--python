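import numpy as np
import pytest

from osteocount.synth import SceneConfig, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


#: Scene profile in which every cell body is above the 500-px size filter,
#: so each ground-truth cell should yield exactly one retained segment.
ABOVE_FILTER_SCENE = SceneConfig(non_radius=(14.0, 17.0))


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic scene with 5 osteoclasts / 20 non-osteoclasts / 3 debris."""
    config = SceneConfig(non_radius=(14.0, 17.0), seed=7)
    image, truth = generate_scene(config)
    return config, image, truth
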