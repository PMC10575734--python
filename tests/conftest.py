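import numpy as np
import pandas as pd
import pytest

from persistkit.io import ExpressionMatrix, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def small_matrix():
    """4 genes x 5 observations with distinct values (no rank ties)."""
    values = pd.DataFrame(
        [
            [5.0, 1.0, 3.2, 0.4, 2.0],
            [4.0, 2.5, 0.1, 3.3, 1.1],
            [1.5, 4.1, 2.2, 2.9, 0.2],
            [0.5, 3.0, 4.4, 1.2, 3.7],
        ],
        index=["CD36", "AGPS", "UGCG", "PEX1"],
        columns=[f"c{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture
def three_gene_set():
    return GeneSet(name="PEROXI", description="test set", genes=("CD36", "AGPS", "UGCG"))
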