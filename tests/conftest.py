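import numpy as np
import pytest

from g3plt import ItemParams


@pytest.fixture
def bank3():
    """The three-item worked-example bank (scaling constant 1)."""
    return ItemParams(a=[0.8, 1.0, 1.2], b=[-1.0, 0.0, 1.0],
                      c=[0.0, 0.05, 0.1], D=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
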