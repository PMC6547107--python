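import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from precisionrct import default_cohort_spec, generate_cohort
from precisionrct.cohort import ParticipantTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Complete-data cohort of 200 participants with the default structure."""
    spec = default_cohort_spec(n_enrolled=200, seed=7)
    spec = dataclasses.replace(spec, miss_rate=0.0, cgm_miss_rate=0.0)
    return generate_cohort(spec)


@pytest.fixture
def missing_cohort():
    """Cohort of 300 with 10% MCAR missingness in non-CGM covariates."""
    spec = default_cohort_spec(n_enrolled=300, seed=11)
    spec = dataclasses.replace(spec, miss_rate=0.10, cgm_miss_rate=0.0)
    return generate_cohort(spec)


def reward_table(y, X, A):
    """Participant table wrapping a directly simulated reward column."""
    df = pd.DataFrame({f"x{j}": X[:, j] for j in range(X.shape[1])})
    df.insert(0, "id", np.arange(1, len(y) + 1))
    df["arm"] = np.asarray(A, dtype=int)
    filler = np.random.default_rng(99).normal(size=(len(y), 6))
    for k, c in enumerate(("hba1c_0", "hba1c_18", "qol_0", "qol_18", "bmiz_0", "bmiz_18")):
        df[c] = filler[:, k]  # inert baselines so no column is degenerate
    df["cgm_complete"] = True
    df["reward"] = y
    kinds = {f"x{j}": "continuous" for j in range(X.shape[1])}
    return ParticipantTable(df, kinds)
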