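import numpy as np
import pandas as pd
import pytest

from zosrec import climate, synth
from zosrec.climate import (
    ExceedanceSpec,
    exceedance_summary,
    fit_offset_model,
    hindcast_bottom_temperature,
    monthly_atmos_summary,
    smooth_series,
    wind_chill,
    wind_components,
)

from conftest import make_wind_frame

TRUE_BETA = {
    "Intercept": 0.4, "airsea": 0.25, "chill": -0.002, "wind3": -0.15,
    "airsea:chill": 1e-4, "airsea:wind3": 0.01, "chill:wind3": 5e-5,
    "airsea:chill:wind3": -2e-6,
}


def synth_offset_frame(rng, days=400, noise=0.0):
    """Daily series whose site-ocean temperature offset follows TRUE_BETA."""
    t = pd.date_range("2012-06-01", periods=days, freq="D")
    doy = t.dayofyear.to_numpy()
    sst = pd.Series(12 + 8 * np.cos(2 * np.pi * (doy - 210) / 365.25), index=t)
    air = sst + rng.normal(1.0, 2.0, days)
    wind = pd.Series(rng.gamma(4.0, 1.2, days), index=t)
    air = pd.Series(air, index=t)
    m = climate.OffsetModel(pd.Series(dtype=float), pd.DataFrame(), 0, 0, 0, 0)
    X = m.design(air - sst, wind_chill(air, wind), wind.rolling(3, min_periods=3).mean())
    offset = sum(TRUE_BETA[c] * X[c].to_numpy() for c in X.columns)
    site = sst + offset + rng.normal(0, noise, days)
    site.iloc[:2] = np.nan  # wind lookback undefined anyway
    return site, sst, air, wind


class TestWindComponents:
    def test_due_westerly(self):
        e, n = wind_components([270.0] * 5)
        assert e == pytest.approx(-1.0)
        assert n == pytest.approx(0.0, abs=1e-12)

    def test_north_and_east_mix(self):
        e, n = wind_components([0.0, 90.0])
        assert (e, n) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_empty_input_warns_and_is_missing(self):
        with pytest.warns(UserWarning):
            e, n = wind_components([])
        assert np.isnan(e) and np.isnan(n)

    @pytest.mark.parametrize("seed", range(4))
    def test_component_vector_never_leaves_unit_disc(self, seed):
        r = np.random.default_rng(seed)
        e, n = wind_components(r.uniform(0, 360, 50))
        assert e**2 + n**2 <= 1.0 + 1e-12


class TestWindChill:
    def test_zero_at_33_degrees(self):
        assert wind_chill(33.0, 7.0) == 0.0

    def test_direct_formula_value(self):
        expected = 1.163 * (10 * np.sqrt(10) + 10.45 - 10) * 33.0
        assert wind_chill(0.0, 10.0) == pytest.approx(expected)

    def test_increasing_in_wind_below_33(self):
        v = np.linspace(0.0, 25.0, 120)
        out = wind_chill(5.0, v)
        assert np.all(np.diff(out) > 0)


class TestSmoothSeries:
    def test_constant_series_unchanged_and_idempotent(self):
        x = pd.Series(3.5, index=pd.date_range("2010-01-01", periods=30))
        once = smooth_series(x)
        assert np.allclose(once, 3.5)
        assert np.allclose(smooth_series(once), once)

    def test_linear_ramp_unchanged_on_interior(self):
        x = pd.Series(np.arange(30.0), index=pd.date_range("2010-01-01", periods=30))
        sm = smooth_series(x)
        assert np.allclose(sm.iloc[3:-3], x.iloc[3:-3])

    def test_impulse_spreads_over_seven_days(self):
        x = pd.Series(0.0, index=pd.date_range("2010-01-01", periods=21))
        x.iloc[10] = 7.0
        sm = smooth_series(x)
        assert np.allclose(sm.iloc[7:14], 1.0)
        assert sm.iloc[6] == 0.0 and sm.iloc[14] == 0.0

    def test_interior_mean_preserved(self, rng):
        x = pd.Series(rng.normal(size=200), index=pd.date_range("2010-01-01", periods=200))
        sm = smooth_series(x)
        # centered window: each interior point is an average, so the global
        # mean shifts only through the edges
        assert sm.iloc[3:-3].mean() == pytest.approx(
            x.rolling(7, center=True).mean().iloc[3:-3].mean())

    def test_even_window_rejected(self):
        x = pd.Series(np.arange(10.0), index=pd.date_range("2010-01-01", periods=10))
        with pytest.raises(ValueError):
            smooth_series(x, window=6)


class TestOffsetModel:
    def test_noiseless_coefficients_recovered_exactly(self, rng):
        site, sst, air, wind = synth_offset_frame(rng, noise=0.0)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        for term, beta in TRUE_BETA.items():
            assert m.params[term] == pytest.approx(beta, rel=1e-6)
        assert m.adj_r2 > 0.999999

    def test_noisy_recovery_within_two_se(self):
        hits = total = 0
        for s in range(60):
            r = np.random.default_rng(s)
            site, sst, air, wind = synth_offset_frame(r, noise=0.5)
            m = fit_offset_model(site, sst, air, wind, presmoothed=True)
            for term, beta in TRUE_BETA.items():
                se = np.sqrt(m.cov.loc[term, term])
                hits += abs(m.params[term] - beta) <= 2 * se
                total += 1
        assert hits / total >= 0.90

    def test_matches_normal_equations_oracle(self, rng):
        site, sst, air, wind = synth_offset_frame(rng, noise=0.3)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        df = pd.DataFrame({
            "offset": site - sst, "airsea": air - sst,
            "chill": wind_chill(air, wind),
            "wind3": wind.rolling(3, min_periods=3).mean(),
        }).dropna()
        X = m.design(df["airsea"], df["chill"], df["wind3"]).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ df["offset"].to_numpy())
        assert np.allclose(beta, m.params[list(m.TERMS)].to_numpy(), rtol=1e-8)

    def test_too_few_days_rejected(self, rng):
        site, sst, air, wind = synth_offset_frame(rng, days=40)
        with pytest.raises(ValueError, match="60"):
            fit_offset_model(site, sst, air, wind, presmoothed=True)


class TestHindcast:
    def test_zero_coefficient_model_returns_sst(self, rng):
        site, sst, air, wind = synth_offset_frame(rng)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        m.params[:] = 0.0
        out, _ = hindcast_bottom_temperature(m, sst, air, wind)
        assert np.allclose(out.iloc[2:], sst.iloc[2:])

    def test_first_two_days_missing(self, rng):
        site, sst, air, wind = synth_offset_frame(rng)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        out, _ = hindcast_bottom_temperature(m, sst, air, wind)
        assert out.iloc[:2].isna().all() and out.iloc[2:].notna().all()

    def test_crosscheck_fraction_at_calibrated_noise(self):
        # sigma chosen so that |error| <= 1 deg C should hold for ~95% of
        # days (2-sigma band at sigma = 0.5); require the reported >= 93%
        r = np.random.default_rng(7)
        site, sst, air, wind = synth_offset_frame(r, days=800, noise=0.5)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        out, report = hindcast_bottom_temperature(m, sst, air, wind, validation=site)
        assert report["frac_within_1C"] >= 0.93

    def test_long_gaps_flagged_not_interpolated(self, rng):
        site, sst, air, wind = synth_offset_frame(rng)
        m = fit_offset_model(site, sst, air, wind, presmoothed=True)
        air2 = air.copy()
        air2.iloc[100:120] = np.nan
        out, report = hindcast_bottom_temperature(m, sst, air2, wind)
        assert out.iloc[100:120].isna().all()
        assert report["long_gaps"] and report["long_gaps"][0][2] >= 8


class TestExceedance:
    def idx(self, start, days):
        return pd.date_range(start, periods=days, freq="D")

    def test_hot_july_fills_both_warm_tails(self):
        t = pd.Series(26.0, index=self.idx("2010-07-01", 31))
        out = exceedance_summary(t).set_index("zone")["proportion"]
        assert out["25C"] == 1.0 and out["20C"] == 1.0
        assert out["10C"] == 0.0 and out["optimal"] == 0.0

    def test_hand_counted_split_month(self):
        vals = np.r_[np.full(15, 8.0), np.full(15, 15.0)]
        t = pd.Series(vals, index=self.idx("2010-04-01", 30))
        out = exceedance_summary(t).set_index("zone")["proportion"]
        assert out["10C"] == 0.5 and out["optimal"] == 0.5

    def test_central_trio_partitions_each_month(self, rng):
        t = pd.Series(rng.uniform(-5, 30, 365), index=self.idx("2010-01-01", 365))
        out = exceedance_summary(t)
        wide = out.pivot_table(index=["year", "month"], columns="zone", values="proportion")
        assert np.allclose(wide["10C"] + wide["optimal"] + wide["20C"], 1.0)
        assert (wide["0C"] <= wide["5C"]).all() and (wide["5C"] <= wide["10C"]).all()
        assert (wide["25C"] <= wide["20C"]).all()

    def test_boundary_values_are_optimal(self):
        t = pd.Series([10.0, 20.0] * 14, index=self.idx("2010-05-01", 28))
        out = exceedance_summary(t).set_index("zone")["proportion"]
        assert out["optimal"] == 1.0
        assert out["10C"] == 0.0 and out["20C"] == 0.0

    def test_missing_interior_month_interpolated_and_tail_flagged(self):
        a = pd.Series(8.0, index=self.idx("2010-01-01", 31))
        c = pd.Series(12.0, index=self.idx("2010-03-01", 31))
        t = pd.concat([a, c])
        out = exceedance_summary(t)
        feb = out[(out["month"] == 2) & (out["zone"] == "10C")]["proportion"].iloc[0]
        assert 0.0 < feb < 1.0  # between January's 1.0 and March's 0.0


class TestAtmosSummary:
    def test_single_observation_month(self):
        t = pd.DatetimeIndex(["2010-03-15 12:00"])
        w = make_wind_frame(t, [6.5], [270.0])
        out = monthly_atmos_summary(w)
        assert out.loc[0, "mWindSpd"] == 6.5
        assert out.loc[0, "eastness"] == pytest.approx(-1.0)

    def test_calm_records_excluded_from_means(self):
        t = pd.date_range("2010-03-01", periods=20, freq="h")
        calm = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        w = make_wind_frame(t, np.r_[np.zeros(10), np.full(10, 5.0)],
                            np.full(20, 180.0), calm=calm)
        out = monthly_atmos_summary(w)
        assert out.loc[0, "mWindSpd"] == 5.0

    def test_all_calm_month_warns_and_is_missing(self):
        t = pd.date_range("2010-03-01", periods=10, freq="h")
        w = make_wind_frame(t, np.zeros(10), np.zeros(10), calm=np.ones(10, bool))
        with pytest.warns(UserWarning, match="calm"):
            out = monthly_atmos_summary(w)
        assert np.isnan(out.loc[0, "mWindSpd"])

    def test_rainfall_is_monthly_total(self):
        t = pd.date_range("2010-03-01", periods=10, freq="h")
        w = make_wind_frame(t, np.full(10, 3.0), np.full(10, 200.0))
        rain = pd.Series(10.0, index=pd.date_range("2010-03-01", periods=31, freq="D"))
        out = monthly_atmos_summary(w, rain)
        assert out.loc[0, "rain"] == 310.0
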