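import numpy as np
import pytest

from scing.data_io import CountMatrix
from scing.synthetic import simulate_expression, simulate_grn


@pytest.fixture
def small_counts() -> CountMatrix:
    """200 cells x 20 genes from a planted DAG, fixed seed."""
    grn = simulate_grn(20, seed=7)
    return simulate_expression(grn, 200, seed=7)


@pytest.fixture
def planted():
    """Planted 20-gene DAG together with 500 simulated cells."""
    grn = simulate_grn(20, seed=3)
    counts = simulate_expression(grn, 500, seed=3)
    return grn, counts


@pytest.fixture
def rng():
    return np.random.default_rng(0)
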