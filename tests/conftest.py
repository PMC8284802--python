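import numpy as np
import pandas as pd
import pytest

from fugue.data_io import ExpressionMatrix
from fugue.features import compute_feature_table
from fugue.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study with strong planted effects."""
    return generate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def feature_table(study):
    return compute_feature_table(study.expression, study.network, study.flags)


@pytest.fixture()
def tiny_expression():
    """3 genes x 4 samples, 2 tissues, hand-checkable values."""
    values = pd.DataFrame(
        {
            "s1": [2.0, 1.0, 7.0],
            "s2": [4.0, 2.0, 7.0],
            "s3": [6.0, 3.0, 7.0],
            "s4": [8.0, 4.0, 7.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
    )
    sample_tissue = pd.Series(
        {"s1": "T1", "s2": "T1", "s3": "T2", "s4": "T2"}, name="tissue"
    )
    return ExpressionMatrix(values=values, sample_tissue=sample_tissue)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
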