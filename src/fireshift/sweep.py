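"""Moving-window calibration/verification of fire-climate regressions.

A model with 1-3 climate predictors is fitted in every contiguous
calibration window (21 years wide by default; a 1902-2008 record gives 87
windows, the first centered on 1912 and the last on 1998) and then used to
predict annual area burned in every year *outside* that window.  Calibration
accuracy (r-squared) and cross-validation skill (coefficient of efficiency)
are traced across window centers; predictor sets are ranked by combining the
median of the two statistics across windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .regression import (RegressionModel, SkillResult, coefficient_of_efficiency,
                         fit_ols)
from .series import AnnualSeries

__all__ = [
    "CalibrationWindow",
    "CalibrationResult",
    "RankEntry",
    "enumerate_calibration_windows",
    "sweep",
    "rank_predictors",
    "parameter_series",
    "overprediction_bias",
    "MovingWindowRegressor",
]


@dataclass(frozen=True)
class CalibrationWindow:
    """A contiguous span of ``width`` years used to calibrate one model."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.width % 2 == 0:
            raise ValueError("window width must be odd so the center is a year")

    @property
    def width(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def center_year(self) -> int:
        return (self.start_year + self.end_year) // 2

    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


@dataclass(frozen=True)
class CalibrationResult:
    """One window's fitted model plus its out-of-window skill."""

    window: CalibrationWindow
    model: RegressionModel
    skill: SkillResult

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return self.model.predictor_names


@dataclass(frozen=True)
class RankEntry:
    """Ranking summary for one predictor set across all windows."""

    predictor_names: tuple[str, ...]
    global_fit: float
    median_r2: float
    median_ce: float
    score_product_of_medians: float
    score_median_of_products: float
    score: float
    score_mode: str
    rank: int


def enumerate_calibration_windows(first_year: int, last_year: int,
                                  width: int = 21) -> list[CalibrationWindow]:
    """All contiguous windows of ``width`` years inside ``first..last``.

    The count is ``(last - first + 1) - width + 1``; 1902-2008 with width 21
    yields 87 windows.
    """
    if width % 2 == 0:
        raise ValueError(f"window width must be odd, got {width}")
    span = last_year - first_year + 1
    if span < width:
        raise ValueError(f"record span {span} yr is shorter than window width {width}")
    return [CalibrationWindow(start, start + width - 1)
            for start in range(first_year, last_year - width + 2)]


def sweep(predictors, response: AnnualSeries, width: int = 21,
          years=None) -> list[CalibrationResult]:
    """Calibrate in every window and cross-validate on all remaining years.

    Validation years are ALL years outside the calibration window, on both
    sides (with a 107-yr record and 21-yr windows: 86 validation years per
    window).
    """
    preds = list(predictors) if isinstance(predictors, (list, tuple)) else [predictors]
    names = tuple(p.name for p in preds)
    if years is not None:
        yrs = np.asarray(years, dtype=np.int64)
    else:
        lo = max([p.first_year for p in preds] + [response.first_year])
        hi = min([p.last_year for p in preds] + [response.last_year])
        if lo > hi:
            raise ValueError("predictors and response have no overlapping years")
        yrs = np.arange(lo, hi + 1)
    lo, hi = int(yrs[0]), int(yrs[-1])
    X = np.column_stack([p.subset(yrs) for p in preds])
    y = response.subset(yrs)

    windows = enumerate_calibration_windows(lo, hi, width)
    if len(windows) == 1:
        raise ValueError(
            "window width equals the full record span: no validation years"
        )
    results: list[CalibrationResult] = []
    for w in windows:
        mask = (yrs >= w.start_year) & (yrs <= w.end_year)
        try:
            model = fit_ols(X[mask], y[mask], predictor_names=names)
            yhat = model.predict(X[~mask])
            skill = coefficient_of_efficiency(y[~mask], yhat)
        except ValueError as exc:
            raise ValueError(
                f"window {w.start_year}-{w.end_year}: {exc}"
            ) from exc
        results.append(CalibrationResult(window=w, model=model, skill=skill))
    return results


def _window_r2(res: CalibrationResult) -> float:
    """Accuracy statistic for ranking: adjusted r2 for multiple regression."""
    m = res.model
    return m.r2_adj if m.r2_adj is not None else m.r2


def rank_predictors(sweeps: dict, global_fits: dict | None = None,
                    score_mode: str = "median_of_products") -> list[RankEntry]:
    """Rank predictor sets by combining calibration accuracy and skill.

    Two score readings are computed for each set and both are reported:

    * ``product_of_medians`` — median r-squared times median CE;
    * ``median_of_products`` — median across windows of (r2_w x CE_w).

    ``score_mode`` selects which one drives the ranking (descending).
    """
    if score_mode not in ("median_of_products", "product_of_medians"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if not sweeps:
        raise ValueError("no sweeps to rank")
    entries = []
    for key, results in sweeps.items():
        if not results:
            raise ValueError(f"empty sweep for predictor set {key!r}")
        r2s = np.array([_window_r2(r) for r in results])
        ces = np.array([r.skill.ce for r in results])
        pom = float(np.median(r2s) * np.median(ces))
        mop = float(np.median(r2s * ces))
        gf = float(global_fits[key]) if global_fits else float("nan")
        entries.append(dict(
            predictor_names=results[0].predictor_names, global_fit=gf,
            median_r2=float(np.median(r2s)), median_ce=float(np.median(ces)),
            score_product_of_medians=pom, score_median_of_products=mop,
            score=mop if score_mode == "median_of_products" else pom,
        ))
    entries.sort(key=lambda e: e["score"], reverse=True)
    return [RankEntry(rank=i + 1, score_mode=score_mode, **e)
            for i, e in enumerate(entries)]


def parameter_series(results: list[CalibrationResult]) -> pd.DataFrame:
    """Per-window trajectories of the standardized slopes, r2 and CE.

    One row per window center, columns ``std_beta_<name>`` per predictor plus
    ``r2``, ``r2_adj`` and ``ce`` — the table plotted against null-model
    envelopes.
    """
    if not results:
        raise ValueError("empty sweep")
    names = results[0].predictor_names
    rows = []
    for r in results:
        row = {"center_year": r.window.center_year,
               "r2": r.model.r2,
               "r2_adj": np.nan if r.model.r2_adj is None else r.model.r2_adj,
               "ce": r.skill.ce}
        for name, sb in zip(names, r.model.std_betas):
            row[f"std_beta_{name}"] = sb
        rows.append(row)
    return pd.DataFrame(rows).set_index("center_year")


def overprediction_bias(model: RegressionModel, predictors,
                        response: AnnualSeries, validation_years) -> float:
    """Mean percent bias of a model's predictions over validation years.

    Computed on the ln-scale response:
    ``100 * mean((yhat_t - y_t) / y_t)``.  Positive values mean the model
    overpredicts.  Years with non-positive ln-scale response (area below
    1 ha) are excluded with a warning since the ratio is undefined there.
    """
    validation_years = np.asarray(validation_years, dtype=np.int64)
    preds = predictors if isinstance(predictors, (list, tuple)) else [predictors]
    X = np.column_stack([p.subset(validation_years) for p in preds])
    y = response.subset(validation_years)
    keep = y > 0
    if not np.all(keep):
        warnings.warn(
            f"excluded {int((~keep).sum())} validation year(s) with non-positive "
            "ln-scale response from the percent-bias computation",
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("no validation years with positive ln-scale response")
    yhat = model.predict(X[keep])
    return float(100.0 * np.mean((yhat - y[keep]) / y[keep]))


def mean_overprediction_bias(models_and_windows, predictors,
                             response: AnnualSeries, validation_years):
    """Across-model mean and sd of percent bias (several calibrated models)."""
    biases = [overprediction_bias(m, predictors, response, validation_years)
              for m in models_and_windows]
    return float(np.mean(biases)), float(np.std(biases, ddof=1)), biases


class MovingWindowRegressor(RegressorMixin, BaseEstimator):
    """Moving-window fire-climate regression, sklearn style.

    Parameters
    ----------
    width : odd int, default 21
        Calibration-window width in years.
    score_mode : {"median_of_products", "product_of_medians"}
        How window r2 and CE combine into the ranking score.

    ``fit(X, y)`` takes a year-indexed DataFrame of annual predictors
    (1-3 columns) and a year-indexed response Series (ln area burned).
    After fitting, ``results_`` holds one :class:`CalibrationResult` per
    window, ``trajectories_`` the per-center statistic table and
    ``global_model_`` the full-record fit used by ``predict``.
    """

    def __init__(self, width: int = 21,
                 score_mode: str = "median_of_products"):
        self.width = width
        self.score_mode = score_mode

    def _to_series(self, X: pd.DataFrame, y: pd.Series | None):
        preds = [AnnualSeries(str(c), np.asarray(X.index, dtype=np.int64),
                              X[c].to_numpy(dtype=float)) for c in X.columns]
        resp = None
        if y is not None:
            y = pd.Series(np.asarray(y, dtype=float), index=X.index) \
                if not isinstance(y, pd.Series) else y
            resp = AnnualSeries(str(y.name or "response"),
                                np.asarray(y.index, dtype=np.int64),
                                y.to_numpy(dtype=float))
        return preds, resp

    def fit(self, X: pd.DataFrame, y):
        if self.width % 2 == 0:
            raise ValueError("width must be odd")
        preds, resp = self._to_series(X, y)
        self.predictors_ = preds
        self.response_ = resp
        self.global_model_ = fit_ols(preds, resp)
        self.results_ = sweep(preds, resp, width=self.width)
        self.trajectories_ = parameter_series(self.results_)
        self.windows_ = [r.window for r in self.results_]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "global_model_"):
            raise RuntimeError("MovingWindowRegressor is not fitted")
        return self.global_model_.predict(np.asarray(X, dtype=float))

    def median_skill(self) -> float:
        return float(np.median([r.skill.ce for r in self.results_]))
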