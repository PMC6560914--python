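import numpy as np
import pandas as pd
import pytest

from survsig.preprocess import ExpressionMatrix
from survsig.synthetic import (
    nested_arm_config,
    planted_pathway_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def planted_bundle():
    """One planted-pathway cohort (hr_per_0.1 = 1.5, n = 300), seed 0."""
    return simulate_cohort(planted_pathway_config(seed=0))


@pytest.fixture(scope="session")
def nested_bundle():
    """Nested protective/risk arm cohort, seed 0."""
    return simulate_cohort(nested_arm_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def collapse_trivially(bundle):
    """Gene-level relative matrix for single-probe bundles (probe Gx_p1)."""
    from survsig.preprocess import rescale_relative

    rel = rescale_relative(bundle.expression)
    rel.values.index = [i.rsplit("_p", 1)[0] for i in rel.values.index]
    return rel


@pytest.fixture()
def toy_expression():
    vals = pd.DataFrame(
        [[4.0, 6.0, 8.0], [5.0, 5.0, 5.0], [7.0, 7.5, 9.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values=vals, scale="log2")
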