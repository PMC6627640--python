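import numpy as np
import pandas as pd
import pytest

from polysig.data_io import ExpressionMatrix, GroupDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """3-gene x 4-sample counts matrix."""
    data = pd.DataFrame(
        [[10, 20, 30, 40], [0, 5, 1, 2], [100, 80, 90, 70]],
        index=["tp53", "BRCA1", "myc"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "counts")


@pytest.fixture
def two_group_design():
    return GroupDesign(
        {"s1": "parental", "s2": "parental", "s3": "resistant", "s4": "resistant"},
        reference_group="parental",
        test_group="resistant",
    )


def make_logcpm(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "logcpm")
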