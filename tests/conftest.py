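import numpy as np
import pytest

from cellsift import CellMapping, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_X(rng):
    vals = rng.normal(size=(30, 8))
    return ExpressionMatrix(
        vals,
        [f"c{i}" for i in range(30)],
        [f"g{j}" for j in range(8)],
    )


@pytest.fixture
def line_mapping():
    """Three cells on a line at coordinates 0, 1, 3."""
    return CellMapping(np.array([[0.0], [1.0], [3.0]]))


@pytest.fixture
def onehot_ab():
    """Labels {a: cells 0,1; b: cell 2}."""
    return CellMapping.from_labels(["a", "a", "b"])
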