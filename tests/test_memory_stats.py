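"""Partial-correlation machinery: oracles, null behavior, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegcarry import memory_stats as ms
from vegcarry import simulate
from vegcarry.core import VegcarryError


class TestLinearDetrend:
    def test_perfect_line_gives_zeros(self):
        out = ms.linear_detrend(2.0 + 0.3 * np.arange(20))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_slope_removes_mean(self):
        v = np.array([5.0, 5.0, 5.0, 5.0])
        np.testing.assert_allclose(ms.linear_detrend(v), 0.0, atol=1e-12)

    def test_residual_trend_vanishes(self, rng):
        v = rng.normal(size=50)
        out = ms.linear_detrend(v)
        slope = np.polyfit(np.arange(50), out, 1)[0]
        assert abs(slope) < 1e-12
        assert abs(out.mean()) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(VegcarryError):
            ms.linear_detrend(np.array([1.0, 2.0]))

    def test_preserves_missing_positions(self):
        v = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        out = ms.linear_detrend(v)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3, 4]]).all()


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        from scipy.stats import pearsonr

        y, x = rng.normal(size=40), rng.normal(size=40)
        res = ms.partial_correlation(y, x)
        r, p = pearsonr(y, x)
        assert res.r_p == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_self_correlation_is_one(self, rng):
        y = rng.normal(size=30)
        c = rng.normal(size=30)
        res = ms.partial_correlation(y, y, controls=[c])
        assert res.r_p == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_residual_and_precision_methods_agree(self, rng):
        # dual-oracle check on random instances, up to 4 controls
        for _ in range(200):
            k = rng.integers(0, 5)
            data = rng.normal(size=(50, 2 + k))
            a = ms.partial_correlation(data[:, 0], data[:, 1], list(data.T[2:]),
                                       method="residual")
            b = ms.partial_correlation(data[:, 0], data[:, 1], list(data.T[2:]),
                                       method="precision")
            assert a.r_p == pytest.approx(b.r_p, abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        # independent reference implementation on one instance
        import pingouin as pg

        data = rng.normal(size=(60, 4))
        df = pd.DataFrame(data, columns=["y", "x", "c1", "c2"])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = ms.partial_correlation(data[:, 0], data[:, 1], [data[:, 2], data[:, 3]])
        assert res.r_p == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_symmetry_in_y_and_x(self, seed):
        g = np.random.default_rng(seed)
        data = g.normal(size=(30, 4))
        a = ms.partial_correlation(data[:, 0], data[:, 1], [data[:, 2], data[:, 3]])
        b = ms.partial_correlation(data[:, 1], data[:, 0], [data[:, 2], data[:, 3]])
        assert a.r_p == pytest.approx(b.r_p, abs=1e-12)

    def test_constant_after_residualization_flagged(self, rng):
        c = rng.normal(size=30)
        y = 2.0 * c + 1.0          # fully explained by the control
        x = rng.normal(size=30)
        res = ms.partial_correlation(y, x, controls=[c])
        assert not res.defined and np.isnan(res.r_p)

    def test_sample_too_small_rejected(self):
        with pytest.raises(VegcarryError, match="too small"):
            ms.partial_correlation(np.ones(5), np.ones(5), [np.ones(5)] * 3)

    def test_listwise_deletion(self, rng):
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        y2, x2 = y.copy(), x.copy()
        y2[3], x2[17] = np.nan, np.nan
        res = ms.partial_correlation(y2, x2)
        keep = np.ones(40, bool)
        keep[[3, 17]] = False
        ref = ms.partial_correlation(y[keep], x[keep])
        assert res.r_p == pytest.approx(ref.r_p)
        assert res.n == 38


class TestSeasonalVgcProfile:
    def test_carryover_recovered_as_dominant_driver(self):
        cfg = simulate.SeasonalSystemConfig(
            n_cells=500, n_years=35, seed=21,
            gamma={"LGS->EGS": 0.0, "EGS->PGS": 0.6, "PGS->LGS": 0.0},
            beta_t=0.0, beta_p=0.0, beta_t_lag=0.0, beta_p_lag=0.0,
            tmp_trend=0.0, ndvi_noise_sd=1.0,
        )
        data = simulate.simulate_seasonal_system(cfg)
        prof = ms.grid_vgc_profiles(data, "PGS")
        ps = prof[prof.driver == "ndvi_ps"]
        assert (ps["r_p"] > 0).mean() >= 0.95
        # carryover is the largest-magnitude driver in most cells
        by_cell = prof.pivot(index="cell_id", columns="driver", values="r_p").abs()
        dominant = (by_cell.idxmax(axis=1) == "ndvi_ps").mean()
        assert dominant >= 0.8

    def test_null_system_type_one_error(self):
        cfg = simulate.SeasonalSystemConfig(
            n_cells=2000, n_years=35, seed=22,
            gamma={"LGS->EGS": 0.0, "EGS->PGS": 0.0, "PGS->LGS": 0.0},
            beta_t=0.0, beta_p=0.0, beta_t_lag=0.0, beta_p_lag=0.0,
            tmp_trend=0.0,
        )
        data = simulate.simulate_seasonal_system(cfg)
        prof = ms.grid_vgc_profiles(data, "PGS", drivers=("ndvi_ps",))
        frac = (prof["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_duplicated_driver_flags_others(self, small_system):
        df = small_system.to_frame()
        one = df[df.cell_id == "cell_0"].copy()
        # overwrite concurrent temperature with the target greenness
        pgs_ndvi = one[(one.variable == "ndvi") & (one.season == "PGS")]
        for _, row in pgs_ndvi.iterrows():
            sel = ((one.variable == "tmp") & (one.season == "PGS")
                   & (one.year == row["year"]))
            one.loc[sel, "value"] = row["value"]
        prof = ms.seasonal_vgc_profile(one, "PGS")
        assert prof.results["tmp"].r_p == pytest.approx(1.0)
        assert not prof.results["ndvi_ps"].defined

    def test_egs_uses_previous_year_lgs(self, small_system):
        # the EGS profile must align preceding greenness with year t-1
        df = small_system.to_frame()
        one = df[df.cell_id == "cell_3"]
        prof = ms.seasonal_vgc_profile(one, "EGS")
        assert prof.results["ndvi_ps"].n == 34  # one year lost to the shift

    def test_detrended_variant_removes_trend_effect(self):
        cfg = simulate.SeasonalSystemConfig(
            n_cells=50, n_years=35, seed=23, tmp_trend=0.1,
        )
        data = simulate.simulate_seasonal_system(cfg)
        raw = ms.grid_vgc_profiles(data, "PGS")
        det = ms.grid_vgc_profiles(data, "PGS", detrend=True)
        assert len(raw) == len(det)
        assert not np.allclose(
            raw.loc[raw.driver == "tmp", "r_p"].to_numpy(),
            det.loc[det.driver == "tmp", "r_p"].to_numpy(),
        )

    def test_too_few_years_rejected(self, small_system):
        df = small_system.to_frame()
        one = df[(df.cell_id == "cell_0") & (df.year < 1990)]
        with pytest.raises(VegcarryError, match="10"):
            ms.seasonal_vgc_profile(one, "PGS")


class TestResidualDriverCorrelation:
    def test_null_r2_matches_expectation(self, rng):
        # under independence, E[R^2] = k / (n - 1)
        n, k, reps = 35, 5, 400
        r2s = []
        for _ in range(reps):
            eps = rng.normal(size=n)
            fac = {f"f{i}": rng.normal(size=n) for i in range(k)}
            _, r2 = ms.residual_driver_correlation(eps, fac)
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx(k / (n - 1), abs=0.03)

    def test_single_factor_explains_residual(self, rng):
        f = rng.normal(size=40)
        eps = f + rng.normal(scale=1e-3, size=40)
        res, r2 = ms.residual_driver_correlation(
            eps, {"f": f, "g": rng.normal(size=40)})
        assert res["f"].r_p > 0.99
        assert r2 > 0.99

    def test_injected_legacy_recovered(self, rng):
        # residual built from previous-year precipitation plus noise: that
        # factor must carry the largest partial correlation
        n = 35
        pre_prev = rng.normal(size=n)
        eps = 0.8 * pre_prev + rng.normal(scale=0.5, size=n)
        factors = {
            "ndvi_prev": rng.normal(size=n),
            "tmp_prev": rng.normal(size=n),
            "pre_prev": pre_prev,
        }
        res, _ = ms.residual_driver_correlation(eps, factors)
        rs = {k: abs(v.r_p) for k, v in res.items()}
        assert max(rs, key=rs.get) == "pre_prev"

    def test_empty_factor_list_rejected(self):
        with pytest.raises(VegcarryError, match="empty"):
            ms.residual_driver_correlation(np.zeros(10), {})


class TestLaggedPacf:
    def test_ar1_lead_profile(self):
        # one long AR(1): lead-1 near phi, higher leads near zero
        x, _ = simulate.simulate_annual_ar(0.4, 10_000, seed=31)
        res = ms.lagged_pacf(x[0], max_lead=3)
        assert res[0].r_p == pytest.approx(0.4, abs=0.03)
        assert abs(res[1].r_p) < 0.03
        assert abs(res[2].r_p) < 0.03

    def test_white_noise_null_rate(self):
        xs, _ = simulate.simulate_annual_ar(0.0, 100, n_series=400, seed=32)
        sig = []
        for i in range(xs.shape[0]):
            res = ms.lagged_pacf(xs[i], max_lead=1)
            sig.append(res[0].p_value < 0.05)
        assert np.mean(sig) == pytest.approx(0.05, abs=0.03)

    def test_perfect_lag1_dependence_gives_unity(self):
        # y_t = y_{t-1} + 1 exactly: lead-1 coefficient is 1
        x = np.cumsum(np.ones(30))
        out = ms.lagged_pacf(x, max_lead=1, detrend=False)
        assert out[0].r_p == pytest.approx(1.0, abs=1e-6)

    def test_climate_controls_absorb_forcing(self, rng):
        # greenness driven purely by climate: controlling climate kills the
        # apparent lag-1 persistence inherited from persistent forcing
        n = 5000
        clim, _ = simulate.simulate_annual_ar(0.7, n, seed=33)
        clim = clim[0]
        y = 1.0 * clim + rng.normal(scale=0.3, size=n)
        naive = ms.lagged_pacf(y, max_lead=1)
        controlled = ms.lagged_pacf(y, climate={"tmp": clim}, max_lead=1)
        assert naive[0].r_p > 0.3
        assert abs(controlled[0].r_p) < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(VegcarryError, match=">= 15"):
            ms.lagged_pacf(np.arange(10.0))

    def test_controls_ledger_lists_smaller_leads(self):
        x, _ = simulate.simulate_annual_ar(0.3, 60, seed=34)
        res = ms.lagged_pacf(x[0], climate={"tmp": np.random.default_rng(0).normal(size=60)},
                             max_lead=3)
        assert res[2].controls[:2] == ["y_lead1", "y_lead2"]
        assert "tmp_t" in res[2].controls and "tmp_t-1" in res[2].controls


class TestSignFrequencySummary:
    def make(self, rs, ps):
        return pd.DataFrame({"r_p": rs, "p_value": ps})

    def test_all_positive_none_significant(self):
        out = ms.sign_frequency_summary(self.make([0.1, 0.2, 0.3], [0.5, 0.6, 0.7]))
        row = out.iloc[0]
        assert row["pct_positive"] == 100.0
        assert row["pct_sig_positive"] == 0.0

    def test_counting(self):
        rs = [0.5, 0.4, 0.3, -0.2, 0.1, -0.1, 0.2, 0.3, -0.4, 0.6]
        ps = [0.01, 0.02, 0.03, 0.5, 0.6, 0.7, 0.8, 0.9, 0.2, 0.3]
        out = ms.sign_frequency_summary(self.make(rs, ps))
        row = out.iloc[0]
        assert row["pct_sig_positive"] == pytest.approx(30.0)
        assert row["pct_positive"] + row["pct_negative"] == pytest.approx(100.0)

    def test_null_significance_rate(self, rng):
        n = 1000
        rs = rng.normal(size=n)
        ps = rng.uniform(size=n)  # p uniform under the null
        out = ms.sign_frequency_summary(self.make(rs, ps))
        row = out.iloc[0]
        sig = row["pct_sig_positive"] + row["pct_sig_negative"]
        assert sig == pytest.approx(5.0, abs=2.0)

    def test_undefined_counted_separately(self):
        out = ms.sign_frequency_summary(
            self.make([0.1, np.nan, -0.2], [0.5, np.nan, 0.6]))
        row = out.iloc[0]
        assert row["n"] == 2 and row["n_undefined"] == 1

    def test_grouped(self):
        df = self.make([0.1, 0.2, -0.3, -0.4], [0.01, 0.5, 0.01, 0.5])
        df["grp"] = ["a", "a", "b", "b"]
        out = ms.sign_frequency_summary(df, group_col="grp").set_index("group")
        assert out.loc["a", "pct_positive"] == 100.0
        assert out.loc["b", "pct_negative"] == 100.0
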