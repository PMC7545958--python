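import numpy as np
import pytest

from rtcdm import table1_design, simulate_dataset
from rtcdm.core import validate_qmatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_qmatrix():
    """6 items × 3 attributes: singletons, pairs, and the full triple."""
    return validate_qmatrix(np.array([
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [0, 1, 1],
        [1, 1, 1],
    ]))


@pytest.fixture(scope="session")
def study1_dataset():
    """One benchmark study-1 replication with rapid guessing."""
    return simulate_dataset(table1_design(0.1), seed=314159)
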