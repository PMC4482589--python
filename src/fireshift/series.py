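"""Annual and daily time-series containers.

Series are deliberately strict: an :class:`AnnualSeries` must cover a gapless
run of years (records are trimmed to their observed span rather than carrying
missing values), and a :class:`DailySeries` must have strictly increasing,
duplicate-free dates.  All analysis code relies on these invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnnualSeries", "DailySeries"]


@dataclass(frozen=True)
class AnnualSeries:
    """A gapless year-indexed real-valued series.

    Parameters
    ----------
    name : str
        Label (metric name or response label).
    years : array-like of int
        Strictly increasing consecutive calendar years.
    values : array-like of float
        One finite value per year.  Units are metric-specific; the fire
        response is carried as ln(ha).
    """

    name: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if years.ndim != 1 or values.ndim != 1:
            raise ValueError("years and values must be one-dimensional")
        if len(years) != len(values):
            raise ValueError(
                f"length mismatch: {len(years)} years vs {len(values)} values"
            )
        if len(years) == 0:
            raise ValueError("series cannot be empty")
        if not np.all(np.diff(years) == 1):
            raise ValueError(
                f"years must be consecutive with no gaps (series {self.name!r})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"missing/non-finite values are not permitted (series {self.name!r}); "
                "trim the series to its observed span instead"
            )
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def value_in(self, year: int) -> float:
        """Value for a single year."""
        if not self.first_year <= year <= self.last_year:
            raise KeyError(f"year {year} outside span of series {self.name!r}")
        return float(self.values[year - self.first_year])

    def subset(self, years: np.ndarray | list[int]) -> np.ndarray:
        """Values for an arbitrary set of years (need not be contiguous)."""
        years = np.asarray(years, dtype=np.int64)
        if years.min() < self.first_year or years.max() > self.last_year:
            raise KeyError(
                f"requested years outside span {self.first_year}-{self.last_year} "
                f"of series {self.name!r}"
            )
        return self.values[years - self.first_year]

    def trim(self, first: int, last: int) -> "AnnualSeries":
        """Restrict to the (inclusive) year range first..last."""
        lo = max(first, self.first_year)
        hi = min(last, self.last_year)
        if lo > hi:
            raise ValueError(
                f"no overlap between {first}-{last} and series span "
                f"{self.first_year}-{self.last_year}"
            )
        sl = slice(lo - self.first_year, hi - self.first_year + 1)
        return AnnualSeries(self.name, self.years[sl], self.values[sl])

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"),
                         name=self.name)

    @classmethod
    def from_pandas(cls, s: pd.Series, name: str | None = None) -> "AnnualSeries":
        return cls(name or (s.name or "series"),
                   np.asarray(s.index, dtype=np.int64),
                   np.asarray(s.values, dtype=np.float64))


def common_span(*series: AnnualSeries) -> tuple[int, int]:
    """Largest year range covered by every series (inclusive)."""
    lo = max(s.first_year for s in series)
    hi = min(s.last_year for s in series)
    if lo > hi:
        raise ValueError("series have no overlapping years")
    return lo, hi


@dataclass(frozen=True)
class DailySeries:
    """A daily real-valued series with strictly increasing dates."""

    name: str
    dates: pd.DatetimeIndex
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=np.float64)
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(dates) == 0:
            raise ValueError("series cannot be empty")
        if dates.has_duplicates:
            raise ValueError(f"duplicate dates in daily series {self.name!r}")
        if not dates.is_monotonic_increasing:
            raise ValueError(f"dates must be strictly increasing ({self.name!r})")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.name)

    @classmethod
    def from_pandas(cls, s: pd.Series, name: str | None = None) -> "DailySeries":
        return cls(name or (s.name or "series"), pd.DatetimeIndex(s.index),
                   np.asarray(s.values, dtype=np.float64))
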