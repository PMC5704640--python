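import numpy as np
import pandas as pd
import pytest

from reosig import ExpressionMatrix


def em(values, genes=None, samples=None, unit="arbitrary") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a nested list (genes x samples)."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            unit=unit)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return em([[1, 2], [0, 5], [3, 3]], genes=["A", "B", "C"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
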