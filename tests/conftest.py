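import numpy as np
import pytest

from pkmeans import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def gaussian_matrix(rng):
    """1000 x 5 i.i.d. standard-normal entries."""
    return DataMatrix(rng.standard_normal((1000, 5)), [f"v{j}" for j in range(5)])


def make_matrix(values, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"v{j}" for j in range(values.shape[1])]
    return DataMatrix(values, names, ids)
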