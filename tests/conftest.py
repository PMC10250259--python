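import numpy as np
import pytest

from actionspace import StudyConfig, gen_ground_truth
from dataclasses import replace


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study for fast end-to-end tests."""
    return replace(
        StudyConfig(),
        n_actions=24,
        n_categories=4,
        min_category_size=4,
        n_redundant=4,
    )


@pytest.fixture(scope="session")
def small_gt(small_config):
    return gen_ground_truth(11, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
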