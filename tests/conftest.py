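import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def binom_3se(p: float, n: int) -> float:
    """Three binomial standard errors for a frequency estimate."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
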