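import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ringwue import climate_prep
from ringwue.climate_prep import (build_annual_climate, drought_filter,
                                  scale_covariates, select_matched_years,
                                  train_test_split, water_year_precip)


def monthly_table(years, precip=10.0, site="S1", seed=None):
    rows = []
    rng = np.random.default_rng(seed) if seed is not None else None
    for y in years:
        for m in range(1, 13):
            p = precip if rng is None else rng.uniform(5, 120)
            rows.append({"site_id": site, "year": y, "month": m,
                         "precip": p, "tmax": 20.0 + m, "pdsi": 0.0})
    return pd.DataFrame(rows)


class TestWaterYear:
    def test_constant_months_sum_to_120(self):
        monthly = monthly_table(range(1990, 1995))
        assert water_year_precip(monthly, "S1", 1992) == pytest.approx(120.0)

    def test_first_year_has_no_water_year(self):
        monthly = monthly_table(range(1990, 1995))
        with pytest.raises(KeyError):
            water_year_precip(monthly, "S1", 1990)
        annual = build_annual_climate(monthly)
        assert 1990 not in set(annual["year"])

    @given(st.floats(min_value=-5, max_value=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, d):
        monthly = monthly_table(range(1990, 1995), seed=8)
        shifted = monthly.assign(precip=monthly["precip"] + d)
        base = water_year_precip(monthly, "S1", 1992)
        assert water_year_precip(shifted, "S1", 1992) == pytest.approx(
            base + 12 * d, rel=1e-12)

    def test_duplicate_months_rejected(self):
        monthly = monthly_table(range(1990, 1992))
        dup = pd.concat([monthly, monthly.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            build_annual_climate(dup)

    def test_june_tmax_and_jja_pdsi(self):
        monthly = monthly_table(range(1990, 1993))
        monthly.loc[monthly["month"].isin([6, 7, 8]), "pdsi"] = [
            -1.0, 0.0, 1.0] * 3
        annual = build_annual_climate(monthly)
        row = annual[annual["year"] == 1991].iloc[0]
        assert row["june_tmax"] == 26.0
        assert row["jja_pdsi"] == pytest.approx(0.0)


class TestDroughtFilter:
    def _obs(self, pdsi_by_year, cohort="Past"):
        return pd.DataFrame({
            "site_id": "S1", "cohort": cohort,
            "year": list(pdsi_by_year),
            "jja_pdsi": [pdsi_by_year[y] for y in pdsi_by_year]})

    def test_four_value_example(self):
        # 0.75 quantile of {-3,-1,0,2} is 0.5: the wettest year (2) drops
        obs = self._obs({2000: -3.0, 2001: -1.0, 2002: 0.0, 2003: 2.0})
        out = drought_filter(obs, q=0.75)
        assert set(out["year"]) == {2000, 2001, 2002}

    def test_q1_is_identity(self):
        obs = self._obs({2000: -3.0, 2001: -1.0, 2002: 0.0, 2003: 2.0})
        out = drought_filter(obs, q=1.0)
        assert len(out) == len(obs)

    def test_keep_wet_flips_direction(self):
        obs = self._obs({2000: -3.0, 2001: -1.0, 2002: 0.0, 2003: 2.0})
        out = drought_filter(obs, q=0.75, keep="wet")
        assert set(out["year"]) == {2001, 2002, 2003}

    def test_small_group_unfiltered(self, caplog):
        obs = self._obs({2000: -3.0, 2001: 2.0})
        with caplog.at_level(logging.WARNING):
            out = drought_filter(obs, q=0.75)
        assert len(out) == 2
        assert "unfiltered" in caplog.text

    def test_groups_filtered_independently(self):
        a = self._obs({2000: -3.0, 2001: -1.0, 2002: 0.0, 2003: 2.0}, "Past")
        b = self._obs({2010: 5.0, 2011: 6.0, 2012: 7.0, 2013: 9.0}, "Modern")
        out = drought_filter(pd.concat([a, b], ignore_index=True), q=0.75)
        assert set(out[out.cohort == "Modern"]["year"]) == {2010, 2011, 2012}


class TestScaling:
    def _obs(self, seed=4, n=60):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "group": np.repeat(["A", "B"], n // 2),
            "wy_precip": rng.uniform(400, 900, n),
            "june_tmax": rng.uniform(22, 29, n),
            "dbh": rng.uniform(5, 50, n)})

    def test_within_group_zscore_identity(self):
        scaled, _ = scale_covariates(self._obs())
        for _, grp in scaled.groupby("group"):
            for col in ("precip_scaled", "tmax_scaled", "dbh_scaled"):
                assert grp[col].mean() == pytest.approx(0.0, abs=1e-10)
                assert grp[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_interaction_is_product_of_zscores(self):
        scaled, _ = scale_covariates(self._obs())
        np.testing.assert_allclose(
            scaled["interaction"],
            scaled["precip_scaled"] * scaled["tmax_scaled"])

    def test_same_raw_value_maps_differently_across_groups(self):
        obs = self._obs()
        obs.loc[obs.index[0], "wy_precip"] = 700.0
        obs.loc[obs.index[-1], "wy_precip"] = 700.0
        scaled, _ = scale_covariates(obs)
        assert (scaled["precip_scaled"].iloc[0]
                != scaled["precip_scaled"].iloc[-1])

    def test_unscale_recovers_raw(self):
        obs = self._obs()
        scaled, params = scale_covariates(obs)
        back = params.unscale(scaled)
        for col in ("wy_precip", "june_tmax", "dbh"):
            np.testing.assert_allclose(back[col], obs[col], atol=1e-9)

    def test_unit_change_gives_identical_zscores(self):
        obs = self._obs()
        cm = obs.assign(wy_precip=obs["wy_precip"] / 10.0)  # mm -> cm
        a, _ = scale_covariates(obs)
        b, _ = scale_covariates(cm)
        np.testing.assert_allclose(a["precip_scaled"], b["precip_scaled"],
                                   atol=1e-12)

    def test_zero_sd_raises_naming_group(self):
        obs = self._obs()
        obs.loc[obs["group"] == "A", "dbh"] = 20.0
        with pytest.raises(ValueError, match="dbh.*A"):
            scale_covariates(obs)

    def test_stored_params_apply_to_new_rows(self):
        obs = self._obs()
        _, params = scale_covariates(obs)
        held, _ = scale_covariates(obs.iloc[:5], params=params)
        mu = params.table.loc["A", "wy_precip_mean"]
        sd = params.table.loc["A", "wy_precip_sd"]
        np.testing.assert_allclose(
            held["precip_scaled"],
            (obs.iloc[:5]["wy_precip"] - mu) / sd)


class TestSplit:
    def _obs(self, n_per=40):
        rows = []
        for site in ("S1", "S2"):
            for cohort in ("Past", "Modern"):
                for i in range(n_per):
                    rows.append({"site_id": site, "cohort": cohort, "i": i})
        return pd.DataFrame(rows)

    def test_partition(self):
        obs = self._obs()
        train, test = train_test_split(obs, frac=0.75, seed=1)
        assert len(train) + len(test) == len(obs)
        assert not set(train.index) & set(test.index)

    def test_reproducible_under_seed(self):
        obs = self._obs()
        a = train_test_split(obs, seed=9)
        b = train_test_split(obs, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_stratum_proportions(self):
        obs = self._obs(n_per=40)
        train, _ = train_test_split(obs, frac=0.75, seed=2)
        counts = train.groupby(["site_id", "cohort"]).size()
        assert (counts == 30).all()

    def test_study_scale_counts(self):
        # at the study's realized fraction, 1503 records split 1124/379
        obs = pd.DataFrame({"site_id": "S1", "cohort": "Past",
                            "i": range(1503)})
        train, test = train_test_split(obs, frac=1124 / 1503, seed=0)
        assert (len(train), len(test)) == (1124, 379)

    def test_bad_frac_rejected(self):
        with pytest.raises(ValueError):
            train_test_split(self._obs(), frac=1.0)


class TestMatchedYears:
    def _monthly(self, years, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for y in years:
            for m in range(1, 13):
                rows.append({"site_id": "S1", "year": y, "month": m,
                             "precip": rng.uniform(10, 100),
                             "tmax": rng.uniform(15, 30),
                             "pdsi": rng.uniform(-4, 4)})
        return pd.DataFrame(rows)

    def test_identical_windows_give_zero_distance(self):
        base = self._monthly(range(1900, 1910), seed=5)
        clone = base.assign(year=base["year"] + 60)
        monthly = pd.concat([base, clone], ignore_index=True)
        pairs = select_matched_years(monthly, (1900, 1909), (1960, 1969),
                                     k=10)
        assert len(pairs) == 10
        np.testing.assert_allclose(pairs["distance"], 0.0, atol=1e-8)

    def test_k1_matches_exhaustive_minimum(self):
        monthly = self._monthly(list(range(1900, 1903))
                                + list(range(1960, 1963)), seed=6)
        pairs = select_matched_years(monthly, (1900, 1902), (1960, 1962), k=1)
        # brute force over all 9 cross pairs in the same PC space
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler
        wide = monthly.pivot_table(index="year", columns="month",
                                   values=["precip", "tmax", "pdsi"])
        z = StandardScaler().fit_transform(wide.to_numpy())
        pcs = PCA(n_components=2).fit_transform(z)
        scores = dict(zip(wide.index, pcs))
        best = min(((np.linalg.norm(scores[p] - scores[m]), p, m)
                    for p in range(1900, 1903) for m in range(1960, 1963)))
        assert pairs.iloc[0]["past_year"] == best[1]
        assert pairs.iloc[0]["modern_year"] == best[2]
        assert pairs.iloc[0]["distance"] == pytest.approx(best[0])

    def test_pairs_are_disjoint(self):
        monthly = self._monthly(range(1900, 1915), seed=7)
        clone = monthly.assign(year=monthly["year"] + 60)
        pairs = select_matched_years(pd.concat([monthly, clone]),
                                     (1900, 1914), (1960, 1974), k=10)
        assert pairs["past_year"].is_unique
        assert pairs["modern_year"].is_unique

    def test_short_window_returns_fewer_with_warning(self, caplog):
        monthly = self._monthly(list(range(1900, 1903))
                                + list(range(1960, 1970)), seed=8)
        with caplog.at_level(logging.WARNING):
            pairs = select_matched_years(monthly, (1900, 1902),
                                         (1960, 1969), k=10)
        assert len(pairs) == 3
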