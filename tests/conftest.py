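import numpy as np
import pytest

from casbind.params import default_parameter_set


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
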