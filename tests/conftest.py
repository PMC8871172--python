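import numpy as np
import pytest

from glaret import ActivationTensor, TransactionDB


@pytest.fixture
def worked_db() -> TransactionDB:
    """{a,b,c}, {a,b}, {a,c}, {b} with a=0, b=1, c=2."""
    return TransactionDB.from_itemsets([{0, 1, 2}, {0, 1}, {0, 2}, {1}])


def random_db(rng: np.random.Generator, max_m: int = 12, max_n: int = 8) -> TransactionDB:
    """A random small transaction database for oracle comparisons."""
    m = int(rng.integers(1, max_m + 1))
    n = int(rng.integers(1, max_n + 1))
    itemsets = []
    for _ in range(m):
        density = rng.uniform(0.1, 0.9)
        itemsets.append({i for i in range(n) if rng.random() < density})
    return TransactionDB.from_itemsets(itemsets)


@pytest.fixture
def tiny_tensor() -> ActivationTensor:
    """2x2x2 tensor with channel pairs (1,1),(2,0) / (0,3),(4,4)."""
    values = np.zeros((2, 2, 2))
    values[0, 0] = (1, 1)
    values[0, 1] = (2, 0)
    values[1, 0] = (0, 3)
    values[1, 1] = (4, 4)
    return ActivationTensor(values)
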