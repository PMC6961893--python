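import numpy as np
import pytest

from svvkit.synthetic import DesignGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid():
    return DesignGrid()
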