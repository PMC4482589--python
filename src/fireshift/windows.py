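"""Seasonal summarization of daily metrics into annual predictors.

Fire-danger and water-balance indices are computed at daily resolution, but
one value per year is needed to regress annual area burned on them.  A
:class:`WindowSpec` describes how the daily record collapses to that annual
value within the fire season (1 May - 1 October):

* ``fixed_end`` — the mean of the ``length_days`` daily values ending on a
  fixed calendar date (inclusive).  The window is anchored on its end date
  and may reach back before the season start when daily data exist there
  (a 90-day mean ending 1 September starts on 4 June).
* ``floating`` — the running ``length_days``-day mean is computed for every
  placement lying fully inside the season, and the maximum (or minimum)
  across placements is taken.  With ``length_days = 1`` this is simply the
  season maximum/minimum of the daily values.

:func:`optimize_window_definition` searches a grid of candidate specs for
the one whose annual summary best explains a response series (full-record
r-squared), mirroring how "optimal time windows" are chosen for each metric.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .series import AnnualSeries, DailySeries

__all__ = [
    "SEASON",
    "WindowSpec",
    "MetricDefinition",
    "seasonal_summary",
    "candidate_window_grid",
    "optimize_window_definition",
    "SeasonalWindowOptimizer",
]

#: Default fire season: 1 May through 1 October (inclusive).
SEASON: tuple[tuple[int, int], tuple[int, int]] = ((5, 1), (10, 1))

#: Default candidate grid (window lengths in days, fixed end dates).
DEFAULT_LENGTHS = (1, 15, 30, 45, 60, 75, 90, 105, 120)
DEFAULT_END_DATES = ((8, 1), (8, 15), (9, 1), (9, 15), (10, 1))


class InvalidWindowSpec(ValueError):
    """Raised when a window specification violates its invariants."""


@dataclass(frozen=True)
class WindowSpec:
    """How a daily series collapses to one annual value.

    mode : ``"fixed_end"`` or ``"floating"``
    statistic : ``"mean"`` or ``"value"`` (point value, length 1 only)
    length_days : window length in days (1 for a point value)
    end_date : (month, day) anchor, fixed_end mode only
    season_extremum : ``"max"``/``"min"`` across placements, floating mode only
    """

    mode: str
    statistic: str = "mean"
    length_days: int = 1
    end_date: tuple[int, int] | None = None
    season_extremum: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_end", "floating"):
            raise InvalidWindowSpec(f"unknown mode {self.mode!r}")
        if self.statistic not in ("mean", "value"):
            raise InvalidWindowSpec(f"unknown statistic {self.statistic!r}")
        if self.length_days < 1:
            raise InvalidWindowSpec("length_days must be a positive integer")
        if self.length_days > 160:
            raise InvalidWindowSpec("length_days must be <= 160")
        if self.statistic == "value" and self.length_days != 1:
            raise InvalidWindowSpec("statistic 'value' requires length_days == 1")
        if self.mode == "fixed_end":
            if self.season_extremum not in (None, "none"):
                raise InvalidWindowSpec("fixed_end windows take no season_extremum")
            if self.end_date is None:
                raise InvalidWindowSpec("fixed_end windows require an end_date")
            m, d = self.end_date
            if not (1 <= m <= 12 and 1 <= d <= 31):
                raise InvalidWindowSpec(f"invalid end_date {self.end_date}")
        else:
            if self.end_date is not None:
                raise InvalidWindowSpec("floating windows take no end_date")
            if self.season_extremum not in ("max", "min"):
                raise InvalidWindowSpec(
                    "floating windows require season_extremum 'max' or 'min'"
                )

    def label(self) -> str:
        if self.mode == "floating":
            return f"{self.length_days}-day {self.season_extremum}"
        m, d = self.end_date
        month = calendar.month_abbr[m]
        if self.length_days == 1:
            return f"1 day, {d} {month}"
        return f"{self.length_days}-day mean, {d} {month}"


@dataclass(frozen=True)
class MetricDefinition:
    """A named climate metric with its optimal seasonal window."""

    name: str
    category: str
    window: WindowSpec
    record_start_year: int

    CATEGORIES = ("fire_danger", "water_balance", "climate")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(
                f"category must be one of {self.CATEGORIES}, got {self.category!r}"
            )


def _season_bounds(year: int, season) -> tuple[pd.Timestamp, pd.Timestamp]:
    (sm, sd), (em, ed) = season
    return pd.Timestamp(year, sm, sd), pd.Timestamp(year, em, ed)


def seasonal_summary(
    daily: DailySeries,
    spec: WindowSpec,
    season: tuple[tuple[int, int], tuple[int, int]] = SEASON,
) -> AnnualSeries:
    """Collapse a daily series to one value per year under ``spec``.

    Years whose daily record does not cover the required days are dropped
    with a warning rather than producing a missing value.
    """
    s = daily.to_pandas()
    out_years: list[int] = []
    out_vals: list[float] = []
    dropped: list[int] = []
    for year in np.unique(daily.dates.year):
        start, end = _season_bounds(int(year), season)
        if spec.mode == "floating":
            seg = s.loc[start:end]
            n_days = (end - start).days + 1
            if len(seg) < n_days:  # gaps inside the season
                dropped.append(int(year))
                continue
            if spec.length_days > n_days:
                raise InvalidWindowSpec(
                    f"floating window of {spec.length_days} days does not fit "
                    f"inside the {n_days}-day season"
                )
            means = np.convolve(
                seg.to_numpy(), np.full(spec.length_days, 1.0 / spec.length_days),
                mode="valid",
            )
            val = means.max() if spec.season_extremum == "max" else means.min()
        else:  # fixed_end: anchored on end_date, may reach before the season
            em, ed = spec.end_date
            end_ts = pd.Timestamp(int(year), em, ed)
            start_ts = end_ts - pd.Timedelta(days=spec.length_days - 1)
            seg = s.loc[start_ts:end_ts]
            if len(seg) < spec.length_days:
                dropped.append(int(year))
                continue
            val = float(seg.to_numpy().mean())
        out_years.append(int(year))
        out_vals.append(float(val))
    if dropped:
        warnings.warn(
            f"{daily.name}: dropped year(s) {dropped} with insufficient daily "
            f"coverage for window {spec.label()!r}",
            stacklevel=2,
        )
    if not out_years:
        raise ValueError(
            f"no year in {daily.name!r} has sufficient coverage for {spec.label()!r}"
        )
    return AnnualSeries(f"{daily.name} [{spec.label()}]",
                        np.array(out_years), np.array(out_vals))


def candidate_window_grid(
    lengths=DEFAULT_LENGTHS,
    end_dates=DEFAULT_END_DATES,
) -> list[WindowSpec]:
    """Enumerate the candidate window search space.

    For each length: a floating max and a floating min; for each
    (length, end date) pair: a fixed-end mean.  The default grid yields
    9x2 floating + 9x5 fixed-end = 63 specs.
    """
    lengths = list(lengths)
    end_dates = [tuple(e) for e in end_dates]
    if not lengths or not end_dates:
        raise ValueError("candidate grid requires non-empty lengths and end_dates")
    if any(l < 1 for l in lengths):
        raise ValueError("window lengths must be positive")
    specs: list[WindowSpec] = []
    for length in lengths:
        stat = "value" if length == 1 else "mean"
        for ext in ("max", "min"):
            specs.append(WindowSpec("floating", statistic="mean" if length > 1 else "mean",
                                    length_days=length, season_extremum=ext))
        for end in end_dates:
            specs.append(WindowSpec("fixed_end", statistic=stat,
                                    length_days=length, end_date=end))
    # dedupe while preserving order
    seen: set[WindowSpec] = set()
    out = []
    for sp in specs:
        if sp not in seen:
            seen.add(sp)
            out.append(sp)
    return out


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def optimize_window_definition(
    daily: DailySeries,
    response: AnnualSeries,
    grid: list[WindowSpec] | None = None,
    season=SEASON,
    category: str = "climate",
    min_overlap: int = 30,
    informative_r2: float = 0.05,
) -> tuple[MetricDefinition, pd.DataFrame]:
    """Pick the window definition whose annual summary best explains the response.

    Every spec in ``grid`` is scored by the full-record r-squared between its
    seasonal summary and the response over their overlapping years; ties break
    toward shorter windows, then fixed-end before floating.  Returns the
    winning :class:`MetricDefinition` and the full score table (one row per
    spec, including a ``no_informative_window`` diagnostic column set when the
    best r-squared is below ``informative_r2``).
    """
    if grid is None:
        grid = candidate_window_grid()
    if not grid:
        raise ValueError("empty candidate grid")

    rows = []
    for spec in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = seasonal_summary(daily, spec, season)
        years = np.intersect1d(summ.years, response.years)
        if len(years) == 0:
            continue
        r2 = _r2(summ.subset(years), response.subset(years))
        rows.append({
            "label": spec.label(), "mode": spec.mode,
            "length_days": spec.length_days,
            "end_date": "" if spec.end_date is None else f"{spec.end_date[0]:02d}-{spec.end_date[1]:02d}",
            "season_extremum": spec.season_extremum or "none",
            "n_years": len(years), "r2": r2, "spec": spec,
        })
    if not rows:
        raise ValueError("no overlapping years between daily record and response")
    table = pd.DataFrame(rows)
    if int(table["n_years"].max()) < min_overlap:
        raise ValueError(
            f"need >= {min_overlap} overlapping years, best available is "
            f"{int(table['n_years'].max())}"
        )
    # tie-break: higher r2, then shorter window, then fixed_end before floating
    order = table.sort_values(
        by=["r2", "length_days", "mode"],
        ascending=[False, True, True],  # 'fixed_end' < 'floating' lexically
        kind="mergesort",
    )
    best = order.iloc[0]
    flagged = bool(best["r2"] < informative_r2)
    table = table.drop(columns="spec").assign(no_informative_window=flagged)
    definition = MetricDefinition(
        name=daily.name, category=category, window=best["spec"],
        record_start_year=int(daily.years[0]),
    )
    return definition, table.sort_values("r2", ascending=False).reset_index(drop=True)


class SeasonalWindowOptimizer(TransformerMixin, BaseEstimator):
    """Estimator wrapper around the optimal-window search.

    ``fit(daily, response)`` selects the best :class:`WindowSpec` for the
    daily metric; ``transform(daily)`` applies it, returning the annual
    summary series.
    """

    def __init__(self, grid=None, season=SEASON, category="climate",
                 min_overlap=30, informative_r2=0.05):
        self.grid = grid
        self.season = season
        self.category = category
        self.min_overlap = min_overlap
        self.informative_r2 = informative_r2

    def fit(self, daily: DailySeries, response: AnnualSeries):
        definition, table = optimize_window_definition(
            daily, response, grid=self.grid, season=self.season,
            category=self.category, min_overlap=self.min_overlap,
            informative_r2=self.informative_r2,
        )
        self.definition_ = definition
        self.best_spec_ = definition.window
        self.scores_ = table
        self.no_informative_window_ = bool(table["no_informative_window"].iloc[0])
        return self

    def transform(self, daily: DailySeries) -> AnnualSeries:
        if not hasattr(self, "best_spec_"):
            raise RuntimeError("SeasonalWindowOptimizer is not fitted")
        return seasonal_summary(daily, self.best_spec_, self.season)
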