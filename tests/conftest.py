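import numpy as np
import pandas as pd
import pytest

from mirsig.io import load_table1_fixture
from mirsig.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_wide(table1):
    return table1.drop(columns=["accession"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_group_matrix(rng):
    """8 samples (4 + 4), 50 features, pure noise around a baseline."""
    samples = [f"A2780_{i}" for i in range(1, 5)] + [f"A2780CR1_{i}" for i in range(1, 5)]
    values = pd.DataFrame(
        7.0 + rng.normal(0, 0.3, size=(50, 8)),
        index=[f"f{i:03d}" for i in range(50)],
        columns=samples,
    )
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in samples})
    return ExpressionMatrix(values, groups, ("A2780", "A2780CR1"))
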