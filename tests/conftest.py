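import numpy as np
import pandas as pd
import pytest

from ceranet import ExpressionMatrix, SimConfig, simulate_cohort
from ceranet.diffexpr import call_differential_expression


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def de_calls(cohort):
    return call_differential_expression(cohort.combined)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, classes=None, conditions=None):
    """Small ExpressionMatrix from a 2-D array, defaulting to mRNA labels and
    a half tumor / half normal split."""
    values = np.asarray(values, float)
    n_mol, n_s = values.shape
    mols = [f"g{i}" for i in range(n_mol)]
    samp = [f"s{i}" for i in range(n_s)]
    if classes is None:
        classes = ["mRNA"] * n_mol
    if conditions is None:
        conditions = ["tumor"] * (n_s // 2) + ["normal"] * (n_s - n_s // 2)
    return ExpressionMatrix(
        pd.DataFrame(values, index=mols, columns=samp),
        pd.Series(classes, index=mols),
        pd.Series(conditions, index=samp),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
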