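"""Season delineation: cycle averaging, slope detection, window rules."""

import numpy as np
import pandas as pd
import pytest

from vegcarry import phenology
from vegcarry.core import VegcarryError
from vegcarry.simulate import PhenoCurveParams, composite_midpoints, simulate_biweekly_ndvi


def biweekly_from_cycle(cycle, years):
    rows = []
    for y in years:
        for p, v in enumerate(cycle, start=1):
            rows.append(("c0", y, p, v))
    return pd.DataFrame(rows, columns=["cell_id", "year", "period", "value"])


class TestClimatologicalCycle:
    def test_identical_years_equal_any_year(self):
        cycle = PhenoCurveParams().curve(composite_midpoints())
        df = biweekly_from_cycle(cycle, [2000, 2001, 2002])
        np.testing.assert_allclose(phenology.climatological_cycle(df), cycle)

    def test_two_offset_years_average(self):
        cycle = PhenoCurveParams().curve(composite_midpoints())
        df = pd.concat([
            biweekly_from_cycle(cycle, [2000]),
            biweekly_from_cycle(cycle + 2.0, [2001]),
        ])
        np.testing.assert_allclose(phenology.climatological_cycle(df), cycle + 1.0)

    def test_matches_per_period_mean_oracle(self):
        df, _ = simulate_biweekly_ndvi(PhenoCurveParams(), n_years=35, seed=8)
        got = phenology.climatological_cycle(df)
        for p in range(1, 25):
            expected = df.loc[df.period == p, "value"].mean()
            assert got[p - 1] == pytest.approx(expected, abs=1e-12)

    def test_all_missing_period_is_error(self):
        cycle = PhenoCurveParams().curve(composite_midpoints())
        df = biweekly_from_cycle(cycle, [2000, 2001])
        df.loc[df.period == 7, "value"] = np.nan
        with pytest.raises(VegcarryError, match="7"):
            phenology.climatological_cycle(df)


class TestDetectSosEos:
    def test_recovers_slope_extrema_of_double_logistic(self):
        # oracle: dense differencing of the analytic noise-free curve
        params = PhenoCurveParams()
        cycle = params.curve(composite_midpoints())
        days = np.arange(1.0, 365.0, 0.01)
        slope = np.gradient(params.curve(days), days)
        true_sos, true_eos = days[np.argmax(slope)], days[np.argmin(slope)]
        got = phenology.detect_sos_eos(cycle)
        assert got.defined
        assert abs(got.sos_day - true_sos) <= 8
        assert abs(got.eos_day - true_eos) <= 8

    def test_constant_cycle_flagged(self):
        got = phenology.detect_sos_eos(np.full(24, 0.3))
        assert not got.defined

    def test_time_reversed_cycle_swaps_roles(self):
        cycle = PhenoCurveParams().curve(composite_midpoints())
        fwd = phenology.detect_sos_eos(cycle)
        rev = phenology.detect_sos_eos(cycle[::-1])
        # reversal mirrors the calendar: the greening phase of the mirrored
        # cycle sits where the senescence phase was
        assert rev.defined
        assert rev.sos_day == pytest.approx(366 - fwd.eos_day, abs=2)
        assert rev.eos_day == pytest.approx(366 - fwd.sos_day, abs=2)

    def test_translation_invariance_in_value(self):
        cycle = PhenoCurveParams().curve(composite_midpoints())
        a = phenology.detect_sos_eos(cycle)
        b = phenology.detect_sos_eos(cycle + 5.0)
        assert (a.sos_day, a.eos_day) == (b.sos_day, b.eos_day)


class TestDefineSeasons:
    def monthly_cycle(self, peak_months, base=0.1, peak=0.8):
        cycle = np.full(12, base)
        for m in peak_months:
            cycle[m - 1] = peak
        return cycle

    def test_march_peak_excluded(self):
        cycle = self.monthly_cycle([3])
        with pytest.raises(phenology.CellExcluded, match="month 3"):
            phenology.define_seasons(60.0, 300.0, cycle)

    def test_standard_window_assignment(self):
        # SOS in May, EOS in September, peak greenness in July-August
        cycle = np.array([.05, .05, .05, .1, .3, .5, .8, .75, .4, .15, .05, .05])
        w = phenology.define_seasons(125.0, 260.0, cycle)  # May 5, Sep 17
        assert w.months["EGS"] == (5, 6)
        assert w.months["PGS"] == (7, 8)
        assert w.months["LGS"] == (9,)
        assert set(w.months["DS"]) == {10, 11, 12, 1, 2, 3, 4}

    def test_short_growing_season_single_month_pgs(self):
        # growing season of 3 months: PGS collapses to the peak month
        cycle = np.array([.05, .05, .05, .05, .05, .3, .8, .3, .05, .05, .05, .05])
        w = phenology.define_seasons(155.0, 240.0, cycle)  # Jun 4 .. Aug 28
        assert w.months["PGS"] == (7,)
        assert w.months["EGS"] == (6,)
        assert w.months["LGS"] == (8,)

    def test_pgs_tie_broken_toward_earlier_pair(self):
        cycle = np.array([.05, .05, .05, .1, .3, .8, .8, .8, .3, .1, .05, .05])
        w = phenology.define_seasons(125.0, 280.0, cycle)
        assert w.months["PGS"] == (6, 7)

    def test_pgs_outside_growing_season_is_structural_error(self):
        # EOS in July but peak-sum pair lands in August: inconsistent cell
        cycle = np.array([.05, .05, .05, .1, .3, .5, .6, .9, .85, .1, .05, .05])
        with pytest.raises(VegcarryError, match="EOS"):
            phenology.define_seasons(125.0, 200.0, cycle)

    def test_windows_always_partition_the_year(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            peak = rng.integers(4, 11)
            cycle = 0.05 + 0.7 * np.exp(-0.5 * (np.arange(1, 13) - peak) ** 2)
            sos = max(30.0, (peak - 2.5) * 30.4)
            eos = min(360.0, (peak + 2.5) * 30.4)
            try:
                w = phenology.define_seasons(sos, eos, cycle)
            except (phenology.CellExcluded, VegcarryError):
                continue
            months = sorted(m for s in w.months.values() for m in s)
            assert months == list(range(1, 13))
            assert max(w.months["EGS"], default=0) < min(w.months["PGS"])
            assert min(w.months["LGS"], default=13) > max(w.months["PGS"])


class TestGppSosEos:
    def test_logistic_greenup_matches_analytic_second_derivative(self):
        # oracle: closed-form argmax of d2/dt2 of a logistic is at
        # t0 - log(2 + sqrt(3)) / k (dense grid evaluation used here)
        k, t0 = 0.15, 120.0
        days = np.arange(1.0, 366.0)
        gpp = 10.0 / (1.0 + np.exp(-k * (days - t0)))
        dense = np.arange(1.0, 366.0, 0.01)
        d2 = np.gradient(np.gradient(10.0 / (1.0 + np.exp(-k * (dense - t0))), dense), dense)
        true_sos = dense[np.argmax(d2)]
        got = phenology.detect_sos_eos_gpp(gpp, lam=1.0)
        assert abs(got.sos_day - true_sos) <= 3

    def test_constant_series_flagged(self):
        got = phenology.detect_sos_eos_gpp(np.full(365, 5.0))
        assert not got.defined

    def test_double_logistic_matches_dense_second_difference_oracle(self):
        # asymmetric growth curve: sharp green-up, gentler decline; the
        # oracle is the dense numerical second derivative of the analytic
        # curve, evaluated independently of the spline
        def curve(d):
            up = 1.0 / (1.0 + np.exp(-0.20 * (d - 120.0)))
            down = 1.0 / (1.0 + np.exp(-0.10 * (d - 270.0)))
            return 12.0 * (up - down)

        days = np.arange(1.0, 366.0)
        dense = np.arange(1.0, 366.0, 0.01)
        d2 = np.gradient(np.gradient(curve(dense), dense), dense)
        true_sos, true_eos = dense[np.argmax(d2)], dense[np.argmin(d2)]
        got = phenology.detect_sos_eos_gpp(curve(days), lam=1.0)
        assert abs(got.sos_day - true_sos) <= 3
        assert abs(got.eos_day - true_eos) <= 3

    def test_excess_missing_days_excluded(self):
        days = np.arange(1.0, 366.0)
        gpp = np.exp(-0.5 * ((days - 183.0) / 40.0) ** 2)
        gpp[:100] = np.nan
        with pytest.raises(phenology.CellExcluded, match="missing"):
            phenology.detect_sos_eos_gpp(gpp)


class TestAggregateSeasonal:
    def windows(self):
        return phenology.SeasonWindows(
            sos_day=125.0, eos_day=273.0, cell_id="c0",
            months={"EGS": (5, 6), "PGS": (7, 8), "LGS": (9,),
                    "DS": (10, 11, 12, 1, 2, 3, 4)},
        )

    def monthly(self, values, variable="ndvi", year=2000):
        return pd.DataFrame({
            "cell_id": "c0", "year": year,
            "month": list(range(1, 13)), "variable": variable,
            "value": values,
        })

    def test_mean_of_member_months(self):
        vals = [np.nan] * 4 + [0.4, 0.6] + [np.nan] * 6
        out = phenology.aggregate_seasonal(self.monthly(vals), {"c0": self.windows()})
        egs = out[(out.season == "EGS")]
        assert egs["value"].iloc[0] == pytest.approx(0.5)

    def test_precipitation_sums(self):
        vals = [0.0] * 6 + [10.0, 20.0] + [30.0] + [0.0] * 3
        out = phenology.aggregate_seasonal(
            self.monthly(vals, variable="pre"), {"c0": self.windows()})
        pgs = out[out.season == "PGS"]
        assert pgs["value"].iloc[0] == pytest.approx(30.0)

    def test_missing_member_month_gives_missing_season(self):
        vals = [0.1] * 12
        df = self.monthly(vals)
        df.loc[df.month == 5, "value"] = np.nan
        out = phenology.aggregate_seasonal(df, {"c0": self.windows()})
        egs = out[out.season == "EGS"]
        assert np.isnan(egs["value"].iloc[0])

    def test_dormancy_attaches_to_following_year(self):
        # October-December of year t fall in the DS paired with year t+1
        frames = [self.monthly([1.0] * 12, year=y) for y in (2000, 2001)]
        df = pd.concat(frames)
        out = phenology.aggregate_seasonal(df, {"c0": self.windows()})
        ds = out[out.season == "DS"].set_index("year")
        assert 2001 in ds.index
        assert ds.loc[2001, "value"] == pytest.approx(1.0)
        # year 2000's DS needs Oct-Dec of 1999, which do not exist
        assert 2000 not in ds.index or np.isnan(ds.loc[2000, "value"])

    def test_matches_month_set_mean_oracle(self, small_system, rng):
        vals = rng.uniform(0.1, 0.9, 12)
        out = phenology.aggregate_seasonal(self.monthly(vals), {"c0": self.windows()})
        w = self.windows()
        for season in ("EGS", "PGS", "LGS"):
            expected = np.mean([vals[m - 1] for m in w.months[season]])
            got = out[(out.season == season) & (out.year == 2000)]["value"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)


def test_full_cell_delineation_recovers_truth():
    params = PhenoCurveParams(anomaly_sd=0.01)
    df, truth = simulate_biweekly_ndvi(params, n_years=35, seed=10)
    w = phenology.delineate_cell(df, cell_id="c0")
    assert abs(w.sos_day - truth["sos_day"]) <= 8
    assert abs(w.eos_day - truth["eos_day"]) <= 8


def test_non_vegetated_cell_excluded():
    params = PhenoCurveParams(baseline=0.02, amplitude=0.05)
    df, _ = simulate_biweekly_ndvi(params, n_years=5, seed=1)
    with pytest.raises(phenology.CellExcluded, match="non-vegetated"):
        phenology.delineate_cell(df, cell_id="c0")
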