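import numpy as np
import pytest

from cfhallmarks import signatures


@pytest.fixture(scope="session")
def sig_catalog():
    """Three well-separated synthetic signature profiles."""
    return signatures.synthetic_signatures(n_signatures=3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
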