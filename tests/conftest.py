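"""Shared fixtures: tiny synthetic cohorts and voxel datasets."""

import numpy as np
import pandas as pd
import pytest

import atnseq as a


def make_cohort_frame(n: int = 6, seed: int = 0) -> pd.DataFrame:
    """A minimal valid cohort table with all required columns."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "age": rng.uniform(62, 80, n).round(1),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.uniform(10, 18, n).round(1),
            "ticv": rng.normal(1450, 120, n).round(1),
            "wmh": rng.uniform(0.5, 8, n).round(2),
            "abeta_ratio": rng.uniform(0.05, 0.12, n).round(4),
            "ptau": rng.uniform(30, 100, n).round(1),
            "ttau": rng.uniform(200, 800, n).round(1),
            "hippocampal_volume": rng.normal(2900, 250, n).round(1),
            "diagnosis": ["NC", "SCD", "MCI", "DAT", "NC", "SCD"][:n]
            if n <= 6
            else None,
        }
    )


@pytest.fixture
def cohort_frame() -> pd.DataFrame:
    return make_cohort_frame()


@pytest.fixture
def ad_groups_20():
    """80 subjects, 20 per AD-continuum group, in canonical sequence order."""
    return np.repeat(list(a.AD_CONTINUUM), 20)


@pytest.fixture
def ach():
    return a.permutation_sequences().get("ACH")


def grouped_outcome(position_means, n_per=5):
    """Noiseless outcome with the given mean at each sequence position."""
    groups = np.repeat(list(a.AD_CONTINUUM), n_per)
    y = np.concatenate([np.full(n_per, m, dtype=float) for m in position_means])
    return y, groups
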