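import numpy as np
import pytest

from methcompare import AggregationMatrix, JunctionMatrixPair
from methcompare.simulate import fig1_pair


@pytest.fixture
def fig1():
    return fig1_pair()


def random_masked_matrix(rng, n=None, m=None, density=None):
    """A random aggregation matrix with at least one observed cell."""
    n = n or rng.integers(2, 12)
    m = m or rng.integers(2, 12)
    density = density if density is not None else rng.uniform(0.2, 0.9)
    mask = rng.random((n, m)) < density
    if not mask.any():
        mask[rng.integers(n), rng.integers(m)] = True
    values = np.where(mask, rng.random((n, m)), np.nan)
    return AggregationMatrix(values, mask)


def random_pair(rng, n=None, m_left=None, m_right=None, density=None):
    n = n or int(rng.integers(3, 15))
    left = random_masked_matrix(rng, n=n, m=m_left or int(rng.integers(2, 8)),
                                density=density)
    right = random_masked_matrix(rng, n=n,
                                 m=m_right or int(rng.integers(2, 8)),
                                 density=density)
    return JunctionMatrixPair(left, right)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
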