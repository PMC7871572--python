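import numpy as np
import pytest

from comhub.synthetic import default_fixture


@pytest.fixture(scope="session")
def benchmark_fixture():
    """The standard synthetic benchmark (expression, regulators, gold)."""
    return default_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
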