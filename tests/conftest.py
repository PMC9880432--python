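import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from lncstage.data_io import ExpressionMatrix, InteractionList, StageAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20230113)


@pytest.fixture
def small_matrix():
    """3 genes x 4 cells, continuous, no duplicates or constants."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[0.0, 1.0, 2.0, 3.0], [5.0, 1.5, 0.5, 2.5], [1.0, 4.0, 0.0, 2.0]],
            index=["LNC1", "MR1", "MR2"],
            columns=["c1", "c2", "c3", "c4"],
        )
    )


@pytest.fixture
def annotated_matrix(rng):
    """Continuous 6 x 20 matrix with roles: 2 lncRNAs, 4 mRNAs."""
    genes = ["LNC1", "LNC2", "MR1", "MR2", "MR3", "MR4"]
    roles = {g: ("lncRNA" if g.startswith("LNC") else "mRNA") for g in genes}
    values = pd.DataFrame(
        rng.standard_normal((6, 20)),
        index=genes,
        columns=[f"c{i}" for i in range(20)],
    )
    return ExpressionMatrix(values, roles)


@pytest.fixture
def priors():
    return InteractionList(
        (("LNC1", "MR1"), ("LNC1", "MR2"), ("LNC2", "MR3"), ("LNC2", "MR4"))
    )


@pytest.fixture
def two_stage_assignment():
    return StageAssignment(
        {f"c{i}": ("early" if i < 10 else "late") for i in range(20)}
    )
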