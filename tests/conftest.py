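import numpy as np
import pytest

from ppsim import RngStream, illustration_model, supremum_abs_derivative, \
    supremum_rate


@pytest.fixture(scope="session")
def sinexp():
    """The built-in study target: exp(0.2 t)(1 + sin t) on (0, 6 pi]."""
    return illustration_model()


@pytest.fixture(scope="session")
def sinexp_sup(sinexp):
    return supremum_rate(sinexp)


@pytest.fixture(scope="session")
def sinexp_lipschitz(sinexp):
    return supremum_abs_derivative(sinexp)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def stream():
    return RngStream(20240901)
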