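import numpy as np
import pytest

from acoustocc import make_worked_example


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def worked_example():
    return make_worked_example()
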