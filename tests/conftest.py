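import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import OTUTable


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); - d(A,B)=2, d(A,C)=d(B,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table():
    """Sample X = {A:2, C:2}, sample Y = {B:4} on taxa A, B, C."""
    return OTUTable(
        pd.DataFrame({"X": [2, 0, 2], "Y": [0, 4, 0]}, index=["A", "B", "C"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_taxa, n_samples, depth=200):
    """Random integer OTU table with no empty samples."""
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack(
        [rng.multinomial(depth, rng.dirichlet(20 * p)) for _ in range(n_samples)]
    )
    counts[0, counts.sum(axis=0) == 0] = 1
    return OTUTable(
        pd.DataFrame(
            counts,
            index=[f"OTU_{i + 1:03d}" for i in range(n_taxa)],
            columns=[f"S{j + 1:02d}" for j in range(n_samples)],
        )
    )
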