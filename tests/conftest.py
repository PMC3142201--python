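import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protquant.model_io import PeptideQuantTable
from protquant.synthetic import simulate_profile_matrix

#: three well-separated blob centers in 5 conditions, 10 sigma apart (sd 0.1)
BLOB_SD = 0.1
BLOB_CENTERS = np.ones((3, 5)) + 10 * BLOB_SD * np.array([
    [0, 0, 0, 0, 0],
    [0, 1, 0, -1, 0],
    [1, 0, -1, 0, 1],
])


@pytest.fixture(scope="session")
def blobs():
    """60 protein profiles in 3 clusters at 10 sigma separation, plus truth."""
    matrix, truth = simulate_profile_matrix([20, 20, 20], 5, BLOB_CENTERS, BLOB_SD, seed=7)
    return matrix, truth.true_cluster


@pytest.fixture
def small_table():
    """Two proteins, two conditions, two replicates each."""
    data = pd.DataFrame({
        "protein": ["P1"] * 8 + ["P2"] * 8,
        "peptide": [f"pep{i}" for i in range(8)] * 2,
        "condition": (["t0"] * 4 + ["t1"] * 4) * 2,
        "replicate": ["r1", "r1", "r2", "r2"] * 4,
        "ratio": [1.0, 1.1, 0.9, 1.05, 2.0, 2.1, 1.9, 2.05,
                  1.0, 1.02, 0.98, 1.01, 1.0, 0.99, 1.03, 0.97],
    })
    return PeptideQuantTable(data)
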