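import numpy as np
import pytest

from hippocirc.fixtures import toy_config
from hippocirc.topology import paper_default_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def toy_cfg():
    return toy_config(seed=7)


@pytest.fixture(scope="session")
def default_cfg():
    return paper_default_config(seed=1)
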