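import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_signed_matrix(n, rng, p_assoc=0.25, p_avoid=0.25):
    """Small random symmetric signed matrix for oracle comparisons."""
    u = rng.random((n, n))
    m = np.zeros((n, n), dtype=np.int8)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    m[upper & (u < p_assoc)] = 1
    m[upper & (u >= p_assoc) & (u < p_assoc + p_avoid)] = -1
    return m + m.T
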