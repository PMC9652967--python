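import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from brcaness import ExpressionMatrix

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def make_matrix(values, scale="log2", cohort="test", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale=scale,
        cohort=cohort,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def random_log2_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(6.0, 1.5, size=(30, 12)))
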