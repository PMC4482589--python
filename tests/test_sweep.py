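import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fireshift as fs
from fireshift.series import AnnualSeries
from fireshift.sweep import (CalibrationWindow, MovingWindowRegressor,
                             enumerate_calibration_windows, mean_overprediction_bias,
                             overprediction_bias, parameter_series,
                             rank_predictors, sweep)


def annual(values, name="x", start=1902):
    values = np.asarray(values, dtype=float)
    return AnnualSeries(name, np.arange(start, start + len(values)), values)


class TestEnumerateWindows:
    def test_study_layout_1902_2008(self):
        windows = enumerate_calibration_windows(1902, 2008, 21)
        assert len(windows) == 87
        assert windows[0].center_year == 1912
        assert (windows[0].start_year, windows[0].end_year) == (1902, 1922)
        assert windows[-1].center_year == 1998
        assert (windows[-1].start_year, windows[-1].end_year) == (1988, 2008)

    def test_shorter_record_1916_start(self):
        assert len(enumerate_calibration_windows(1916, 2008, 21)) == 73

    def test_exact_fit_single_window(self):
        assert len(enumerate_calibration_windows(1902, 1922, 21)) == 1

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            enumerate_calibration_windows(1902, 2008, 20)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            enumerate_calibration_windows(2000, 2010, 21)

    @given(first=st.integers(1800, 2000), span=st.integers(21, 200),
           width=st.sampled_from([21, 31, 41]))
    def test_count_formula(self, first, span, width):
        if span < width:
            span = width
        windows = enumerate_calibration_windows(first, first + span - 1, width)
        assert len(windows) == span - width + 1
        assert all(w.width == width for w in windows)
        assert all(w.center_year == (w.start_year + w.end_year) // 2
                   for w in windows)


class TestSweep:
    def test_constant_relationship_has_skill(self, constant_dataset):
        climate, ln_area, truth = constant_dataset
        results = sweep([climate], ln_area)
        assert len(results) == 87
        ces = np.array([r.skill.ce for r in results])
        assert (ces > 0).mean() >= 0.9
        assert all(r.skill.n_validation == 86 for r in results)
        med_r2 = np.median([r.model.r2 for r in results])
        assert abs(med_r2 - 0.5) < 0.25  # generating r2 ~ 0.5 with zeros injected

    def test_full_span_window_errors(self):
        x = annual(np.random.default_rng(0).standard_normal(21))
        y = annual(np.arange(21.0) + x.values, name="y")
        with pytest.raises(ValueError, match="validation"):
            sweep([x], y, width=21)

    def test_altered_regime_yields_negative_ce(self):
        # models calibrated inside the doubled-slope regime lack skill outside
        ces = []
        for seed in range(30):
            spec = fs.altered_relationship_spec(seed=seed, zero_burn_rate=0.0)
            climate, area, truth = fs.generate_scenario(spec)
            ln = fs.log_transform_area(area)
            final = climate.trim(1988, 2008)
            model = fs.fit_ols([final], ln.trim(1988, 2008))
            early_years = np.arange(1902, 1985)
            yhat = model.predict(climate.subset(early_years)[:, None])
            ces.append(fs.coefficient_of_efficiency(
                ln.subset(early_years), yhat).ce)
        assert np.median(ces) < 0

    def test_propagates_window_errors_with_window_tag(self):
        x = annual(np.ones(40))  # zero-variance predictor
        y = annual(np.arange(40.0), name="y")
        with pytest.raises(ValueError, match=r"window 1902-1922"):
            sweep([x], y, width=21)


class TestRankPredictors:
    def make_results(self, r2s, ces):
        # fabricate CalibrationResult-like sweeps through real fits is heavy;
        # use light stand-ins with the attributes ranking reads
        class M:
            def __init__(self, r2):
                self.r2 = r2
                self.r2_adj = None
                self.predictor_names = ("x",)

        class S:
            def __init__(self, ce):
                self.ce = ce

        class R:
            def __init__(self, r2, ce):
                self.model = M(r2)
                self.skill = S(ce)
                self.predictor_names = ("x",)

        return [R(a, b) for a, b in zip(r2s, ces)]

    def test_single_set_is_rank_one(self):
        entries = rank_predictors({"x": self.make_results([0.2], [0.1])})
        assert entries[0].rank == 1

    def test_dominance_orders_consistently(self):
        a = self.make_results([0.5, 0.6, 0.7], [0.3, 0.4, 0.5])
        b = self.make_results([0.4, 0.5, 0.6], [0.2, 0.3, 0.4])
        for mode in ("median_of_products", "product_of_medians"):
            entries = rank_predictors({"A": a, "B": b}, score_mode=mode)
            assert entries[0].predictor_names == ("x",)
            assert entries[0].score > entries[1].score

    def test_two_score_modes_worked_example(self):
        res = self.make_results([0.4, 0.5, 0.6], [0.1, 0.3, 0.2])
        entry = rank_predictors({"x": res})[0]
        assert entry.score_product_of_medians == pytest.approx(0.5 * 0.2)
        assert entry.score_median_of_products == pytest.approx(
            np.median([0.04, 0.15, 0.12]))

    def test_modes_agree_when_statistics_constant(self):
        res = self.make_results([0.5] * 5, [0.3] * 5)
        entry = rank_predictors({"x": res})[0]
        assert entry.score_product_of_medians == pytest.approx(
            entry.score_median_of_products)

    def test_order_invariance(self, constant_dataset):
        climate, ln_area, _ = constant_dataset
        rng = np.random.default_rng(3)
        other = AnnualSeries("noise", climate.years,
                             rng.standard_normal(len(climate)))
        s1 = sweep([climate], ln_area)
        s2 = sweep([other], ln_area)
        r_ab = rank_predictors({"climate": s1, "noise": s2})
        r_ba = rank_predictors({"noise": s2, "climate": s1})
        by_name_ab = {e.predictor_names: (e.rank, e.score) for e in r_ab}
        by_name_ba = {e.predictor_names: (e.rank, e.score) for e in r_ba}
        assert by_name_ab == by_name_ba

    def test_empty_sweep_errors(self):
        with pytest.raises(ValueError):
            rank_predictors({"x": []})
        with pytest.raises(ValueError):
            rank_predictors({})


class TestParameterSeries:
    def test_deterministic_relationship_gives_unit_std_beta(self):
        x = annual(np.sin(np.arange(60.0)))
        y = annual(2.0 * x.values, name="y")
        table = parameter_series(sweep([x], y, width=21))
        np.testing.assert_allclose(table["std_beta_x"], 1.0, atol=1e-8)

    def test_constant_relationship_fluctuates_around_truth(self, constant_dataset):
        climate, ln_area, truth = constant_dataset
        table = parameter_series(sweep([climate], ln_area))
        # generating standardized beta = b1*sd_x/sd_y ~ 1/sqrt(2) ~ 0.71
        assert abs(np.median(table["std_beta_climate"]) - 0.71) < 0.2

    def test_altered_regime_shows_level_shift(self):
        # with noise_sd=1: standardized slope ~1/sqrt(2)=0.71 in the early
        # regime and ~2/sqrt(5)=0.89 once the window sits in the doubled-slope
        # regime
        spec = fs.altered_relationship_spec(seed=5, zero_burn_rate=0.0)
        climate, area, _ = fs.generate_scenario(spec)
        ln = fs.log_transform_area(area)
        table = parameter_series(sweep([climate], ln))
        early = table.loc[table.index < 1960, "std_beta_climate"].mean()
        late = table.loc[table.index >= 1995, "std_beta_climate"].mean()
        assert late > early + 0.05


class TestOverpredictionBias:
    def test_zero_for_perfect_predictions(self):
        x = annual(np.arange(1.0, 61.0))
        y = annual(2.0 + 0.1 * x.values, name="y")
        model = fs.fit_ols([x], y)
        bias = overprediction_bias(model, [x], y, np.arange(1902, 1922))
        assert bias == pytest.approx(0.0, abs=1e-9)

    def test_twenty_percent_inflation_is_definitional(self):
        years = np.arange(1902, 1962)
        y = AnnualSeries("y", years, np.linspace(5.0, 9.0, 60))
        # a fake model predicting exactly 1.2*y
        class Inflator:
            def predict(self, X):
                return 1.2 * X[:, 0]
        x_as_y = AnnualSeries("x", years, y.values)
        bias = overprediction_bias(Inflator(), [x_as_y], y, years)
        assert bias == pytest.approx(20.0)

    def test_recent_calibration_overpredicts_earlier_years(self):
        biases = []
        for seed in range(20):
            spec = fs.altered_relationship_spec(seed=seed, zero_burn_rate=0.0)
            climate, area, _ = fs.generate_scenario(spec)
            ln = fs.log_transform_area(area)
            model = fs.fit_ols([climate.trim(1988, 2008)], ln.trim(1988, 2008))
            biases.append(overprediction_bias(
                model, [climate], ln, np.arange(1902, 1962)))
        assert np.median(biases) > 0

    def test_mean_and_sd_across_models(self):
        x = annual(np.arange(1.0, 61.0))
        y = annual(2.0 + 0.1 * x.values, name="y")
        m = fs.fit_ols([x], y)
        mean, sd, biases = mean_overprediction_bias(
            [m, m], [x], y, np.arange(1902, 1922))
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)


class TestMovingWindowRegressor:
    def test_fit_exposes_sweep_results(self, constant_dataset):
        climate, ln_area, _ = constant_dataset
        X = pd.DataFrame({"climate": climate.values},
                         index=pd.Index(climate.years, name="year"))
        est = MovingWindowRegressor(width=21).fit(X, ln_area.to_pandas())
        assert len(est.results_) == 87
        assert est.trajectories_.shape[0] == 87
        pred = est.predict(X)
        assert pred.shape == (107,)
        # get_params/set_params round-trip
        est2 = MovingWindowRegressor().set_params(**est.get_params())
        assert est2.get_params() == est.get_params()

    def test_even_width_rejected(self, constant_dataset):
        climate, ln_area, _ = constant_dataset
        X = pd.DataFrame({"climate": climate.values}, index=climate.years)
        with pytest.raises(ValueError, match="odd"):
            MovingWindowRegressor(width=20).fit(X, ln_area.to_pandas())
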