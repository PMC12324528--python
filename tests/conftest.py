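import numpy as np
import pandas as pd
import pytest

from somamod.extraction import ExpressionMatrix
from somamod.synthetic import Block, BlockSpec, make_toy_annotation, simulate_expression


@pytest.fixture
def toy_world():
    """Annotation table, alias table and symbol-space collection."""
    return make_toy_annotation(seed=7)


@pytest.fixture
def two_block_matrix():
    """Planted blocks of 20 and 12 (r=0.8) over 30 background features."""
    spec = BlockSpec(blocks=[Block(20, 0.8), Block(12, 0.8)],
                     n_background=30, n_samples=500, seed=11)
    return simulate_expression(spec)


@pytest.fixture
def small_expression():
    """A tiny handmade 6-sample x 4-feature matrix with repeat visits."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(rng.standard_normal((6, 4)),
                          index=[f"S{i}" for i in range(6)],
                          columns=["100-1", "200-2", "300-3", "400-4"])
    return ExpressionMatrix(
        values=values,
        participant_ids=np.array(["P1", "P1", "P2", "P2", "P3", "P4"]),
        visit_dates=np.array(["2009-05-01", "2005-02-01", "2010-01-01",
                              "2010-01-01", "2011-06-01", "2012-07-01"]),
    )
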