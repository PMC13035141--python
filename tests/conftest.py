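import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from uvdemand import SyntheticTruth, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SHARE_COLS = ["share_m_0_5", "share_f_0_5", "share_m_6_17", "share_f_6_17",
              "share_m_18_49", "share_f_18_49", "share_m_gt49", "share_f_gt49"]


def make_records(cig_expenditure, cig_quantity, total_expenditure,
                 cluster_id=None, year=None, weight=None, hh_size=None):
    """Minimal canonical household-wave frame for unit tests."""
    n = len(cig_expenditure)
    df = pd.DataFrame({
        "household_id": np.arange(n),
        "cluster_id": cluster_id if cluster_id is not None else np.zeros(n, int),
        "year": year if year is not None else np.full(n, 2017),
        "weight": weight if weight is not None else np.ones(n),
        "cig_expenditure": np.asarray(cig_expenditure, float),
        "cig_quantity": np.asarray(cig_quantity, float),
        "total_expenditure": np.asarray(total_expenditure, float),
        "hh_size": hh_size if hh_size is not None else np.full(n, 4),
        "n_male": np.full(n, 2),
        "head_female": np.zeros(n, int),
        "head_educ_years": np.full(n, 5),
        "max_educ_years": np.full(n, 8),
        "urban": np.zeros(n, int),
    })
    for c in SHARE_COLS:
        df[c] = 1.0 / len(SHARE_COLS)
    return df


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth(seed=42)


@pytest.fixture(scope="session")
def survey_df(default_truth):
    """Full study-scale synthetic survey (400 clusters x 15 households x 3
    waves) shared across tests."""
    df, _ = generate(default_truth)
    return df


@pytest.fixture(scope="session")
def small_survey():
    """Small, fast synthetic survey (50 clusters x 8 households x 3 waves)."""
    truth = SyntheticTruth(seed=7, n_clusters=50, households_per_cluster=8)
    df, t = generate(truth)
    return df, t


@pytest.fixture(scope="session")
def all_consumer_truth():
    """Everyone consumes and shares sit near 0.5: exact-fit regime for the
    budget-share equation and clean error-moment checks."""
    return SyntheticTruth(
        seed=11, participation_rate=1.0, alpha0=0.5 - 0.0066 * 8.12,
        share_floor=0.0, sigma00=0.01, sigma10=0.025, sigma11=0.25,
        gamma0=np.zeros(20), theta=0.01,
    )
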