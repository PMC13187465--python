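import numpy as np
import pandas as pd
import pytest

from qalbench.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def large_cohort():
    """One big calibrated cohort shared by the convergence checks."""
    return generate_cohort(CohortSpec(n=200_000, seed=20260928))


@pytest.fixture(scope="session")
def clinic_cohort():
    """Study-sized calibrated cohort (n=200)."""
    return generate_cohort(CohortSpec(n=200, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def expand_table(a, b, c, d):
    """Patient-level frame reproducing a 2x2 table (risk factor x, outcome y)."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return pd.DataFrame({"x": x.astype(int), "y": y.astype(int)})
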