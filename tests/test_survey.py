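"""Data model, I/O and preprocessing: deflation, recall harmonisation,
unit values, budget shares, weighted descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from uvdemand import (
    ConfigurationError,
    DataInconsistencyError,
    PipelineConfig,
    ValidationError,
    compute_unit_value,
    deflate,
    describe,
    load_survey,
    preprocess,
    to_weekly,
)
from uvdemand.survey import wmean, wquantile, wsd

from conftest import make_records


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

class TestLoadSurvey:
    def test_three_row_fixture_roundtrip(self, tmp_path):
        df = make_records([40, 0, 30], [20, 0, 3], [1000, 800, 600])
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        out = preprocess(load_survey(path), PipelineConfig())
        assert len(out) == 3
        np.testing.assert_allclose(out["budget_share"], [0.04, 0.0, 0.05])
        np.testing.assert_allclose(out["unit_value"].to_numpy(),
                                   [2.0, np.nan, 10.0])

    def test_column_map_renames_source_columns(self, tmp_path):
        df = make_records([40], [20], [1000]).rename(
            columns={"cig_expenditure": "cigexp"})
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="cig_expenditure"):
            load_survey(path)
        cfg = PipelineConfig(column_map={"cigexp": "cig_expenditure"})
        assert len(load_survey(path, cfg)) == 1

    def test_negative_quantity_names_offending_row(self, tmp_path):
        df = make_records([40, 10], [20, -1], [1000, 900])
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match=r"cig_quantity.*\[1\]"):
            load_survey(path)

    def test_missing_total_expenditure_dropped_with_ids(self, tmp_path):
        df = make_records([40, 10, 5], [20, 5, 2], [1000, np.nan, 700])
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        out = load_survey(path)
        assert len(out) == 2
        assert out.attrs["dropped_missing_total"] == [1]

    def test_share_sum_violation_rejected(self, tmp_path):
        df = make_records([0], [0], [500])
        df["share_m_0_5"] = 0.9
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="sum to 1"):
            load_survey(path)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

class TestTransforms:
    @pytest.mark.parametrize("annual, divisor, weekly", [
        (5200.0, 52.0, 100.0),
        (365.0, 365.0 / 7.0, 7.0),
        (0.0, 52.0, 0.0),
    ])
    def test_to_weekly(self, annual, divisor, weekly):
        assert to_weekly(annual, divisor) == pytest.approx(weekly)

    def test_unit_value_forced_and_absent(self):
        assert compute_unit_value(40.0, 20.0) == pytest.approx(2.0)
        assert np.isnan(compute_unit_value(0.0, 0.0))

    def test_unit_value_inconsistent_pair_raises(self):
        with pytest.raises(DataInconsistencyError):
            compute_unit_value(10.0, 0.0)

    def test_deflate_base_year_identity_and_forced_ratio(self):
        df = make_records([110, 100], [11, 10], [1100, 1000],
                          year=[2016, 2017])
        cpi = {2016: 110.0, 2017: 100.0}
        out = deflate(df, cpi, 2017)
        np.testing.assert_allclose(out["cig_expenditure"], [100.0, 100.0])
        np.testing.assert_allclose(out["total_expenditure"], [1000.0, 1000.0])

    def test_deflate_idempotent(self):
        df = make_records([110], [11], [1100], year=[2016])
        cpi = {2016: 110.0, 2017: 100.0}
        once = deflate(df, cpi, 2017)
        twice = deflate(once, cpi, 2017)
        pd.testing.assert_frame_equal(once, twice)

    def test_deflate_missing_year_raises(self):
        df = make_records([1], [1], [10], year=[2015])
        with pytest.raises(ConfigurationError, match="2015"):
            deflate(df, {2017: 100.0}, 2017)

    @given(ratio=st.floats(0.5, 2.0))
    def test_deflation_preserves_budget_shares(self, ratio):
        df = make_records([40, 80], [20, 16], [1000, 1600], year=[2016, 2016])
        shares = df["cig_expenditure"] / df["total_expenditure"]
        out = deflate(df, {2016: 100.0, 2017: 100.0 * ratio}, 2017)
        np.testing.assert_allclose(
            out["cig_expenditure"] / out["total_expenditure"], shares)


# ---------------------------------------------------------------------------
# record-level invariants after preprocessing
# ---------------------------------------------------------------------------

def test_share_times_total_recovers_cig_expenditure(survey_df):
    c = survey_df["budget_share"] * survey_df["total_expenditure"]
    np.testing.assert_allclose(c, survey_df["cig_expenditure"], rtol=1e-10)


def test_unit_value_absent_iff_nonconsumer(survey_df):
    consuming = survey_df["cig_quantity"] > 0
    assert survey_df.loc[consuming, "unit_value"].notna().all()
    assert survey_df.loc[~consuming, "unit_value"].isna().all()
    assert (survey_df.loc[~consuming, "cig_expenditure"] == 0).all()


# ---------------------------------------------------------------------------
# weighted descriptives
# ---------------------------------------------------------------------------

class TestDescribe:
    def test_equal_weight_mean_of_shares(self):
        df = make_records([20, 40], [10, 20], [1000, 1000])
        table = describe(df, PipelineConfig())
        assert table.loc["budget_share", "mean"] == pytest.approx(0.03)

    def test_weighted_mean_forced(self):
        df = make_records([0, 4], [0, 4], [1, 1], weight=[1.0, 3.0])
        table = describe(df, PipelineConfig())
        assert table.loc["cig_expenditure | consuming", "mean"] == pytest.approx(4.0)
        # unconditional weighted mean of expenditure: (1*0 + 3*4)/4 = 3
        assert wmean(df["cig_expenditure"], df["weight"]) == pytest.approx(3.0)

    def test_mean_unit_value_differs_from_ratio_of_means(self):
        # heterogeneous fixture: per-record unit values 2, 5, 10
        df = make_records([40, 50, 30], [20, 10, 3], [1000, 1000, 1000])
        table = describe(df, PipelineConfig())
        mean_uv = table.loc["unit_value | consuming", "mean"]
        ratio = df["cig_expenditure"].sum() / df["cig_quantity"].sum()
        assert mean_uv == pytest.approx(17.0 / 3.0)
        assert ratio == pytest.approx(120.0 / 33.0)
        assert mean_uv != pytest.approx(ratio)

    def test_unit_weights_match_unweighted_moments(self, small_survey):
        df, _ = small_survey
        unit = df.copy()
        unit["weight"] = 1.0
        weighted = describe(unit, PipelineConfig(weighted_describe=True))
        unweighted = describe(df, PipelineConfig(weighted_describe=False))
        pd.testing.assert_frame_equal(weighted, unweighted)

    def test_all_zero_weights_rejected(self):
        df = make_records([1], [1], [10], weight=[0.0])
        with pytest.raises(ValidationError, match="weights"):
            describe(df, PipelineConfig())

    def test_cluster_design_rows(self, small_survey):
        df, truth = small_survey
        table = describe(df, PipelineConfig())
        assert table.loc["n_clusters", "n"] == truth.n_clusters
        assert table.loc["obs_per_cluster", "mean"] == pytest.approx(
            len(df) / truth.n_clusters)


def test_weighted_quantile_matches_numpy_for_unit_weights():
    rng = np.random.default_rng(0)
    x = rng.normal(size=501)
    w = np.ones_like(x)
    for q in (0.1, 0.5, 0.9):
        assert wquantile(x, w, q) == pytest.approx(np.quantile(x, q), abs=0.02)


def test_weighted_sd_matches_numpy_for_unit_weights():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    assert wsd(x, np.ones_like(x)) == pytest.approx(np.std(x, ddof=1))
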