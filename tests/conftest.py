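import numpy as np
import pytest

from txnsim import ExpressionParams, TranscriptionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return TranscriptionParams()


@pytest.fixture
def short_gene():
    """A 200-nt template: fast to simulate, same kinetics."""
    return TranscriptionParams(N=200)


@pytest.fixture
def expression_params():
    return ExpressionParams()
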