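import numpy as np
import pytest

from plinet.connectivity import ConnectivityMatrix
from plinet.montage import CANONICAL_16


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pli_matrix(rng, n=16, labels=None, low=0.05, high=0.95):
    """A random symmetric PLI-like matrix with zero diagonal."""
    if labels is None:
        labels = CANONICAL_16[:n]
    vals = rng.uniform(low, high, size=(n, n))
    vals = np.triu(vals, k=1)
    vals = vals + vals.T
    return ConnectivityMatrix(values=vals, channel_labels=labels)


@pytest.fixture
def random_matrix_factory(rng):
    def make(n=16, **kw):
        return random_pli_matrix(rng, n=n, **kw)
    return make
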