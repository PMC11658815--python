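import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lpdsub.data_io import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_counts(rng):
    vals = rng.integers(0, 400, size=(50, 10))
    return CountMatrix(
        vals,
        [f"g{i}" for i in range(50)],
        [f"s{i}" for i in range(10)],
    )


@pytest.fixture
def small_expr(rng):
    vals = rng.normal(5, 1.5, size=(30, 12))
    return ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(30)],
        [f"s{i}" for i in range(12)],
    )
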