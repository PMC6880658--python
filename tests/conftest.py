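import numpy as np
import pandas as pd
import pytest

from lldnet.data_io import BAI_COLS, MADRS_COLS, CohortTable
from lldnet.network import GlassoConfig
from lldnet.synthetic import generate_cohort, preset_lld


def make_cohort_df(n=40, seed=0, with_bai_items=False):
    """Small hand-rolled valid cohort frame for I/O and unit tests."""
    rng = np.random.default_rng(seed)
    data = {"subject_id": [f"T{i:03d}" for i in range(n)]}
    for c in MADRS_COLS:
        data[c] = rng.integers(0, 7, size=n)
    if with_bai_items:
        items = rng.integers(0, 4, size=(n, 21))
        for j, c in enumerate(BAI_COLS):
            data[c] = items[:, j]
        data["bai_sum"] = items.sum(axis=1)
    else:
        data["bai_sum"] = rng.integers(0, 64, size=n)
    data["age"] = rng.uniform(60, 90, size=n).round(1)
    data["sex"] = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    data["education_years"] = rng.uniform(0, 16, size=n).round(1)
    data["flags"] = ""
    data["group"] = ""
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def baseline_cohort():
    table, gold = generate_cohort(preset_lld("baseline_lld"), seed=11)
    return table, gold


@pytest.fixture(scope="session")
def confounded_cohort():
    table, gold = generate_cohort(preset_lld("confounded_anxiety"), seed=11)
    return table, gold


@pytest.fixture
def fast_glasso():
    """Short penalty path for permutation-heavy tests."""
    return GlassoConfig(n_lambda=10)


@pytest.fixture
def toy_cohort():
    return CohortTable(make_cohort_df())
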