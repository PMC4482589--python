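import numpy as np
import pandas as pd
import pytest

from fireshift.series import AnnualSeries, DailySeries
from fireshift.simulate import generate_daily_metric, paired_response_from_window
from fireshift.windows import (InvalidWindowSpec, SEASON, WindowSpec,
                               candidate_window_grid, optimize_window_definition,
                               seasonal_summary, SeasonalWindowOptimizer)


def make_daily(years, fn, name="metric"):
    """Daily series over full calendar years with value fn(date)."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    return DailySeries(name, dates, np.array([fn(d) for d in dates], dtype=float))


SEASON_DAYS = (pd.Timestamp(2001, *SEASON[1]) - pd.Timestamp(2001, *SEASON[0])).days + 1


class TestWindowSpec:
    def test_floating_requires_extremum(self):
        with pytest.raises(InvalidWindowSpec):
            WindowSpec("floating", length_days=30)

    def test_fixed_end_requires_end_date(self):
        with pytest.raises(InvalidWindowSpec):
            WindowSpec("fixed_end", length_days=30)

    def test_fixed_end_rejects_extremum(self):
        with pytest.raises(InvalidWindowSpec):
            WindowSpec("fixed_end", length_days=30, end_date=(9, 1),
                       season_extremum="max")

    def test_length_bound(self):
        with pytest.raises(InvalidWindowSpec):
            WindowSpec("floating", length_days=161, season_extremum="max")


class TestSeasonalSummary:
    def test_constant_series_gives_constant(self):
        daily = make_daily([2000, 2001], lambda d: 7.0)
        for spec in (WindowSpec("floating", length_days=30, season_extremum="max"),
                     WindowSpec("fixed_end", length_days=90, end_date=(9, 1)),
                     WindowSpec("fixed_end", statistic="value", length_days=1,
                                end_date=(9, 1))):
            out = seasonal_summary(daily, spec)
            np.testing.assert_allclose(out.values, 7.0)

    def test_floating_max_matches_brute_force(self):
        # value = day-of-season counter 1, 2, 3, ... within each year
        start = pd.Timestamp(2000, *SEASON[0])
        daily = make_daily([2000], lambda d: (d - start).days + 1
                           if start <= d <= pd.Timestamp(2000, *SEASON[1]) else 0.0)
        spec = WindowSpec("floating", length_days=3, season_extremum="max")
        out = seasonal_summary(daily, spec)
        season_vals = np.arange(1, SEASON_DAYS + 1, dtype=float)
        brute = max(season_vals[i:i + 3].mean()
                    for i in range(len(season_vals) - 2))
        assert out.values[0] == pytest.approx(brute)
        assert brute == pytest.approx(season_vals[-3:].mean())

    def test_point_value_on_1_sep(self):
        daily = make_daily([2000], lambda d: 7.5 if (d.month, d.day) == (9, 1) else 1.0)
        spec = WindowSpec("fixed_end", statistic="value", length_days=1,
                          end_date=(9, 1))
        assert seasonal_summary(daily, spec).values[0] == 7.5

    def test_fixed_end_window_reaches_before_season(self):
        # 90-day mean ending 1 Sep starts 4 Jun -- inside season; 120-day
        # mean ending 1 Aug starts 4 Apr -- before 1 May, still computable
        daily = make_daily([2000], lambda d: float(d.dayofyear))
        spec = WindowSpec("fixed_end", length_days=120, end_date=(8, 1))
        out = seasonal_summary(daily, spec)
        end = pd.Timestamp(2000, 8, 1).dayofyear
        expected = np.arange(end - 119, end + 1).mean()
        assert out.values[0] == pytest.approx(expected)

    def test_year_with_gaps_dropped_with_warning(self):
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        keep = ~((dates.year == 2000) & (dates.month == 7))  # hole in July 2000
        daily = DailySeries("m", dates[keep], np.ones(int(keep.sum())))
        spec = WindowSpec("floating", length_days=15, season_extremum="max")
        with pytest.warns(UserWarning, match="2000"):
            out = seasonal_summary(daily, spec)
        np.testing.assert_array_equal(out.years, [2001])

    def test_floating_max_ge_min_everywhere(self):
        daily = generate_daily_metric(range(2000, 2010), seed=3)
        for length in (1, 15, 60):
            mx = seasonal_summary(daily, WindowSpec("floating", length_days=length,
                                                    season_extremum="max"))
            mn = seasonal_summary(daily, WindowSpec("floating", length_days=length,
                                                    season_extremum="min"))
            assert np.all(mx.values >= mn.values)

    def test_full_season_window_collapses_max_min_to_season_mean(self):
        daily = generate_daily_metric(range(2000, 2005), seed=4)
        mx = seasonal_summary(daily, WindowSpec("floating", length_days=SEASON_DAYS,
                                                season_extremum="max"))
        mn = seasonal_summary(daily, WindowSpec("floating", length_days=SEASON_DAYS,
                                                season_extremum="min"))
        np.testing.assert_allclose(mx.values, mn.values)


class TestCandidateGrid:
    def test_single_length_single_end(self):
        specs = candidate_window_grid(lengths=[30], end_dates=[(9, 1)])
        assert len(specs) == 3
        modes = sorted((s.mode, s.season_extremum or "") for s in specs)
        assert modes == [("fixed_end", ""), ("floating", "max"), ("floating", "min")]

    def test_default_grid_has_63_specs(self):
        specs = candidate_window_grid()
        assert len(specs) == 63
        assert len(set(specs)) == 63

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            candidate_window_grid(lengths=[])


class TestOptimizeWindow:
    def test_recovers_generating_window(self):
        daily = generate_daily_metric(range(1960, 2009), seed=11)
        truth = WindowSpec("floating", length_days=30, season_extremum="min")
        response = paired_response_from_window(daily, truth, beta=2.0,
                                               noise_sd=0.05, seed=12)
        definition, table = optimize_window_definition(daily, response)
        assert definition.window == truth
        assert table["r2"].iloc[0] > 0.99

    def test_white_noise_response_flagged_uninformative(self):
        daily = generate_daily_metric(range(1960, 2009), seed=21)
        rng = np.random.default_rng(22)
        response = AnnualSeries("noise", np.arange(1960, 2009), rng.standard_normal(49))
        _, table = optimize_window_definition(daily, response)
        assert table["r2"].max() < 0.25
        if table["r2"].max() < 0.05:
            assert bool(table["no_informative_window"].iloc[0])

    def test_single_spec_grid(self):
        daily = generate_daily_metric(range(1960, 2009), seed=31)
        spec = WindowSpec("fixed_end", length_days=30, end_date=(9, 1))
        response = paired_response_from_window(daily, spec, beta=1.0)
        definition, table = optimize_window_definition(daily, response, grid=[spec])
        assert definition.window == spec
        assert len(table) == 1

    def test_r2_invariant_to_affine_rescaling(self):
        daily = generate_daily_metric(range(1960, 2009), seed=41)
        truth = WindowSpec("floating", length_days=45, season_extremum="max")
        response = paired_response_from_window(daily, truth, beta=1.5,
                                               noise_sd=0.1, seed=42)
        d1, t1 = optimize_window_definition(daily, response)
        rescaled = DailySeries(daily.name, daily.dates, 3.0 * daily.values - 100.0)
        d2, t2 = optimize_window_definition(rescaled, response)
        assert d1.window == d2.window
        np.testing.assert_allclose(
            t1.sort_values("label")["r2"].to_numpy(),
            t2.sort_values("label")["r2"].to_numpy(), atol=1e-10)

    def test_insufficient_overlap_errors(self):
        daily = generate_daily_metric(range(2000, 2005), seed=51)
        response = AnnualSeries("r", np.arange(2000, 2005), np.arange(5.0))
        with pytest.raises(ValueError, match="overlapping years"):
            optimize_window_definition(daily, response)

    def test_estimator_fit_transform(self):
        daily = generate_daily_metric(range(1960, 2009), seed=61)
        truth = WindowSpec("floating", length_days=30, season_extremum="min")
        response = paired_response_from_window(daily, truth, beta=2.0,
                                               noise_sd=0.05, seed=62)
        opt = SeasonalWindowOptimizer().fit(daily, response)
        assert opt.best_spec_ == truth
        summ = opt.transform(daily)
        assert len(summ) == 49
        # sklearn params round-trip
        assert SeasonalWindowOptimizer(**opt.get_params()).get_params() == opt.get_params()
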