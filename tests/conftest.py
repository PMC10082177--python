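import numpy as np
import pytest

from amsriver import LifeHistoryParams, generate_riverscape


@pytest.fixture(scope="session")
def small_riverscape():
    """A 9-patch riverscape (6 natal headwaters, 3 mainstem) for unit tests."""
    return generate_riverscape(6, 3, (5_000, 30_000), seed=1)


@pytest.fixture(scope="session")
def batch_riverscape():
    """A 12-patch riverscape with ~1,300 natal capacity for batch tests."""
    return generate_riverscape(8, 4, (8_000, 30_000), seed=11)


@pytest.fixture
def lh():
    return LifeHistoryParams()


@pytest.fixture
def rng():
    return np.random.default_rng(123)
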