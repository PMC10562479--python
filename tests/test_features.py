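"""DRR, accumulated heat and the lag-specified feature table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import heatlag as hl
from heatlag.features import LagSpec, build_feature_table, feature_count


def _mortality(dates, counts):
    return pd.DataFrame({"date": pd.to_datetime(dates), "count": counts})


class TestDRR:
    def test_two_day_toy(self):
        drr = hl.compute_drr(_mortality(["2009-07-01", "2009-07-02"], [2, 4]))
        np.testing.assert_allclose(drr["drr"], [2 / 3, 4 / 3])

    def test_constant_counts_give_unit_drr(self):
        dates = pd.date_range("2009-07-01", periods=10)
        drr = hl.compute_drr(_mortality(dates, [7] * 10))
        np.testing.assert_allclose(drr["drr"], 1.0)

    def test_each_season_normalises_independently(self, target_mortality):
        m, _ = target_mortality
        drr = hl.compute_drr(m)
        yearly = drr.groupby(pd.to_datetime(drr["date"]).dt.year)["drr"].mean()
        np.testing.assert_allclose(yearly, 1.0, atol=1e-9)

    def test_zero_death_season_names_the_year(self):
        dates = list(pd.date_range("2009-07-01", periods=3)) + list(
            pd.date_range("2010-07-01", periods=3)
        )
        with pytest.raises(ValueError, match="2010"):
            hl.compute_drr(_mortality(dates, [3, 2, 1, 0, 0, 0]))


class TestAcTmax30:
    def test_hand_computed_toy(self):
        w = pd.DataFrame({
            "date": pd.date_range("2009-07-01", periods=5),
            "tmax": [31.0, 29.0, 33.0, 30.0, 32.0],
        })
        acc = hl.compute_actmax30(w)
        np.testing.assert_allclose(acc, [1.0, 1.0, 4.0, 4.0, 6.0])
        assert acc.iloc[-1] == 6.0

    def test_no_exceedance_is_zero(self):
        w = pd.DataFrame({"date": pd.date_range("2009-07-01", periods=6),
                          "tmax": [25.0, 30.0, 28.0, 29.9, 27.0, 30.0]})
        assert (hl.compute_actmax30(w) == 0).all()

    def test_resets_each_season(self):
        dates = list(pd.date_range("2009-07-01", periods=2)) + list(
            pd.date_range("2010-07-01", periods=2)
        )
        w = pd.DataFrame({"date": pd.to_datetime(dates), "tmax": [32.0, 33.0, 31.0, 31.0]})
        np.testing.assert_allclose(hl.compute_actmax30(w), [2.0, 5.0, 1.0, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(20.0, 40.0), min_size=2, max_size=62))
    def test_nondecreasing_within_season(self, tmax):
        w = pd.DataFrame({"date": pd.date_range("2009-07-01", periods=len(tmax)),
                          "tmax": tmax})
        acc = hl.compute_actmax30(w).to_numpy()
        assert (np.diff(acc) >= -1e-12).all()


class TestFeatureTable:
    def test_column_names_and_order(self, one_season_weather):
        table = build_feature_table(one_season_weather, LagSpec(3, 2, 2))
        assert list(table.columns) == [
            "date",
            "Tmax", "TmaxPre2", "TmaxPre3", "TmaxDiffPre1", "TmaxDiffPre2",
            "TmaxDiffPre3", "AcTmax30",
            "Vap", "VapPre2", "VapDiffPre1", "VapDiffPre2",
            "Pres", "PresPre2", "PresDiffPre1", "PresDiffPre2",
            "Rain", "DOW",
        ]
        assert isinstance(table["DOW"].dtype, pd.CategoricalDtype)
        assert len(table["DOW"].dtype.categories) == 7

    def test_column_count_formula(self, one_season_weather):
        # the full per-element expansion: levels Pre2..PreN plus diffs
        # DiffPre1..DiffPreN; the single-first-difference variant gives the
        # 37-column layout for the (8, 9, 14) lag specification
        spec = LagSpec(8, 9, 14)
        assert feature_count(spec, "full") == 65
        assert feature_count(spec, "first") == 37
        for mode in ("full", "first"):
            table = build_feature_table(one_season_weather, spec, diff_mode=mode)
            assert table.shape[1] - 1 == feature_count(spec, mode)

    def test_lagged_values_and_differences(self, one_season_weather):
        spec = LagSpec(3, 2, 2)
        table = build_feature_table(one_season_weather, spec)
        tmax = one_season_weather["tmax"].to_numpy()
        row = table.iloc[0]
        i = one_season_weather.index[one_season_weather["date"] == row["date"]][0]
        assert row["TmaxPre2"] == tmax[i - 2]
        assert row["TmaxDiffPre1"] == pytest.approx(tmax[i] - tmax[i - 1])

    def test_equal_consecutive_tmax_has_zero_diff(self):
        dates = pd.date_range("2009-07-01", periods=10)
        w = pd.DataFrame({"date": dates, "tmax": 31.0, "vap": 25.0,
                          "pres": 1009.0, "rain": 0.0})
        table = build_feature_table(w, LagSpec(2, 2, 2))
        assert (table["TmaxDiffPre1"] == 0).all()

    def test_rows_without_history_are_dropped(self, target_weather):
        spec = LagSpec(8, 9, 14)
        table = build_feature_table(target_weather, spec)
        years = pd.to_datetime(table["date"]).dt.year
        assert (table.groupby(years.to_numpy()).size() == 62 - 14).all()
        assert not table.drop(columns=["date"]).isna().any().any()

    def test_no_leakage_from_future_days(self, one_season_weather):
        spec = LagSpec(3, 2, 2)
        table = build_feature_table(one_season_weather, spec)
        cut = one_season_weather["date"].iloc[30]
        corrupted = one_season_weather.copy()
        mask = corrupted["date"] > cut
        corrupted.loc[mask, ["tmax", "vap", "pres", "rain"]] = 999.0
        table2 = build_feature_table(corrupted, spec)
        keep = table["date"] <= cut
        pd.testing.assert_frame_equal(
            table.loc[keep].reset_index(drop=True),
            table2.loc[keep].reset_index(drop=True),
        )

    def test_date_translation_leaves_non_dow_features_unchanged(self, one_season_weather):
        shifted = one_season_weather.copy()
        shifted["date"] = pd.to_datetime(shifted["date"]) + pd.DateOffset(years=2)
        a = build_feature_table(one_season_weather, LagSpec(3, 2, 2))
        b = build_feature_table(shifted, LagSpec(3, 2, 2))
        pd.testing.assert_frame_equal(
            a.drop(columns=["date", "DOW"]), b.drop(columns=["date", "DOW"])
        )

    def test_lag_longer_than_season_is_an_error(self):
        dates = pd.date_range("2009-07-01", periods=10)
        w = pd.DataFrame({"date": dates, "tmax": 31.0, "vap": 25.0,
                          "pres": 1009.0, "rain": 0.0})
        with pytest.raises(ValueError, match="season"):
            build_feature_table(w, LagSpec(12, 2, 2))


def test_lagspec_bounds_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        LagSpec(0, 2, 2)
    with pytest.raises(ValueError):
        LagSpec(2, 15, 2)
    spec = LagSpec(8, 9, 14)
    spec.to_yaml(tmp_path / "lags.yaml")
    assert LagSpec.from_yaml(tmp_path / "lags.yaml") == spec
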