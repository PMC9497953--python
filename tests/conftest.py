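import numpy as np
import pytest

from riskgame import Params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return Params()


@pytest.fixture
def quick_params():
    """Small run sizes for fast structural tests."""
    return Params(rounds=60, stable_window=20)
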