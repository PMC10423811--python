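import numpy as np
import pandas as pd
import pytest

from nephrosig import ExpressionMatrix, SampleTable, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230731)


@pytest.fixture()
def small_matrix():
    """5 genes x 4 samples with known values."""
    df = pd.DataFrame(
        {
            "S1": [2.0, 5.0, 8.0, 1.0, 7.0],
            "S2": [4.0, 5.0, 6.0, 2.0, 7.5],
            "S3": [6.0, 5.0, 7.0, 3.0, 6.5],
            "S4": [8.0, 5.0, 9.0, 4.0, 8.0],
        },
        index=pd.Index(["G1", "G2", "G3", "G4", "G5"], name="gene"),
    )
    return ExpressionMatrix(df)


@pytest.fixture()
def small_samples():
    meta = pd.DataFrame(
        {
            "cohort": ["c1"] * 4,
            "compartment": ["glomerular"] * 4,
            "group": ["LN", "LN", "LD", "LD"],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return SampleTable(meta)
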