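"""Synthetic fire-climate datasets with known generating truth.

The generator mirrors the conceptual regimes a fire-climate record can move
through: a single constant relationship, a shift in climate itself (same
response function, different climate moments), an altered relationship (same
climate, different regression parameters), or both at once.  Records default
to 107 years labeled 1902-2008 with period boundaries at 1943 and 1985, a
log-linear response

    ln(area) = beta0_p + beta1_p * climate_t + Normal(0, noise_sd),

climate drawn iid Normal(mean_p, sd_p) per period (annual climate series in
such records show little serial correlation), a small fraction of zero-burn
years (3%, injected by zeroing the smallest generated areas so the truth
record stays interpretable), and full determinism under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import AnnualSeries, DailySeries
from .windows import WindowSpec, seasonal_summary, SEASON

__all__ = [
    "ScenarioSpec",
    "constant_spec",
    "climate_shift_spec",
    "altered_relationship_spec",
    "combined_spec",
    "generate_scenario",
    "generate_daily_metric",
    "generate_null_dataset",
    "ar1_series",
]

SCENARIOS = ("constant_relationship", "climate_shift",
             "altered_relationship", "combined")

# Default generating conditions: intercept 8 ln-ha (~3000 ha in a typical
# year), unit slope per climate sd, noise sd 1 ln-ha => full-record r2 ~ 0.5.
_B0, _B1, _NOISE = 8.0, 1.0, 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic regime experiment."""

    scenario: str
    n_years: int = 107
    start_year: int = 1902
    period_boundaries: tuple[int, ...] = (1943, 1985)
    climate_mean: tuple[float, ...] = (0.0, 0.0, 0.0)
    climate_sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    beta0: tuple[float, ...] = (_B0, _B0, _B0)
    beta1: tuple[float, ...] = (_B1, _B1, _B1)
    noise_sd: float = _NOISE
    zero_burn_rate: float = 0.03
    climate_ar1: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        np_ = len(self.period_boundaries) + 1
        for name in ("climate_mean", "climate_sd", "beta0", "beta1"):
            if len(getattr(self, name)) != np_:
                raise ValueError(f"{name} needs one value per period ({np_})")
        bps = self.period_boundaries
        last = self.start_year + self.n_years - 1
        if any(not self.start_year < b <= last for b in bps) or list(bps) != sorted(bps):
            raise ValueError("period boundaries must be increasing interior years")
        if not 0.0 <= self.zero_burn_rate < 0.5:
            raise ValueError("zero_burn_rate must be in [0, 0.5)")
        if not 0.0 <= self.climate_ar1 <= 0.25:
            raise ValueError("climate_ar1 must be in [0, 0.25] (low-autocorrelation regime)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        betas_equal = (len(set(self.beta0)) == 1 and len(set(self.beta1)) == 1)
        moments_equal = (len(set(self.climate_mean)) == 1
                         and len(set(self.climate_sd)) == 1)
        if self.scenario == "constant_relationship" and not (betas_equal and moments_equal):
            raise ValueError("constant_relationship requires equal betas and climate moments")
        if self.scenario == "climate_shift" and not betas_equal:
            raise ValueError("climate_shift requires betas equal across periods")
        if self.scenario == "altered_relationship" and not moments_equal:
            raise ValueError("altered_relationship requires equal climate moments")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def period_index(self) -> np.ndarray:
        idx = np.zeros(self.n_years, dtype=np.int64)
        for b in self.period_boundaries:
            idx += (self.years >= b).astype(np.int64)
        return idx


def constant_spec(seed=None, **kw) -> ScenarioSpec:
    return ScenarioSpec("constant_relationship", seed=seed, **kw)


def climate_shift_spec(shift: float = -1.0, seed=None, **kw) -> ScenarioSpec:
    """Middle period's climate mean shifted by ``shift`` sd (default: less
    fire-conducive mid-century climate)."""
    return ScenarioSpec("climate_shift", climate_mean=(0.0, shift, 0.0),
                        seed=seed, **kw)


def altered_relationship_spec(seed=None, **kw) -> ScenarioSpec:
    """Slope doubled and intercept raised by one noise sd in the final
    (1985-2008, 24-yr) regime: the amplified-response signature."""
    return ScenarioSpec("altered_relationship",
                        beta0=(_B0, _B0, _B0 + _NOISE),
                        beta1=(_B1, _B1, 2.0 * _B1), seed=seed, **kw)


def combined_spec(shift: float = -1.0, seed=None, **kw) -> ScenarioSpec:
    return ScenarioSpec("combined", climate_mean=(0.0, shift, 0.0),
                        beta0=(_B0, _B0, _B0 + _NOISE),
                        beta1=(_B1, _B1, 2.0 * _B1), seed=seed, **kw)


def ar1_series(n: int, phi: float, sd: float = 1.0,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> np.ndarray:
    """Stationary AR(1) draws with marginal sd ``sd``."""
    rng = rng or np.random.default_rng(seed)
    eps_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, eps_sd)
    return x


def generate_scenario(spec: ScenarioSpec):
    """Generate (climate AnnualSeries, area_ha AnnualSeries, truth dict)."""
    rng = np.random.default_rng(spec.seed)
    years = spec.years
    pidx = spec.period_index()
    means = np.asarray(spec.climate_mean)[pidx]
    sds = np.asarray(spec.climate_sd)[pidx]
    if spec.climate_ar1 > 0:
        climate = means + sds * ar1_series(spec.n_years, spec.climate_ar1, rng=rng)
    else:
        climate = rng.normal(means, sds)
    b0 = np.asarray(spec.beta0)[pidx]
    b1 = np.asarray(spec.beta1)[pidx]
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_years)
    ln_area = b0 + b1 * climate + noise
    area = np.exp(ln_area)
    n_zero = int(round(spec.zero_burn_rate * spec.n_years))
    zero_years: list[int] = []
    if n_zero > 0:
        smallest = np.argsort(area)[:n_zero]
        area = area.copy()
        area[smallest] = 0.0
        zero_years = sorted(int(years[i]) for i in smallest)
    truth = {
        "spec": spec,
        "beta0": b0, "beta1": b1, "noise": noise,
        "ln_area_pre_zero": ln_area,
        "zero_years": zero_years,
        "period_index": pidx,
    }
    return (AnnualSeries("climate", years, climate),
            AnnualSeries("area_ha", years, area),
            truth)


def generate_null_dataset(beta0: float = _B0, beta1: float = _B1,
                          r2_target: float = 0.5, n_years: int = 107,
                          seed: int | None = None, start_year: int = 1902,
                          zero_burn_rate: float = 0.0):
    """Constant-relationship dataset with an analytically chosen noise level.

    With unit-variance climate, ``noise_sd = |beta1| * sqrt((1-r2)/r2)``
    makes the expected full-record r-squared equal ``r2_target``.
    """
    if not 0.0 < r2_target < 1.0:
        raise ValueError("r2_target must be in (0, 1)")
    noise_sd = abs(beta1) * np.sqrt((1.0 - r2_target) / r2_target)
    spec = ScenarioSpec(
        "constant_relationship", n_years=n_years, start_year=start_year,
        period_boundaries=_default_boundaries(start_year, n_years),
        beta0=(beta0,) * 3, beta1=(beta1,) * 3, noise_sd=float(noise_sd),
        zero_burn_rate=zero_burn_rate, seed=seed,
    )
    return generate_scenario(spec)


def _default_boundaries(start_year: int, n_years: int) -> tuple[int, int]:
    """Boundaries at the canonical fractions of the record (1943/1985 for
    a 1902-2008 record)."""
    last = start_year + n_years - 1
    if start_year <= 1943 and 1985 <= last:
        return (1943, 1985)
    b1 = start_year + max(2, int(0.38 * n_years))
    b2 = start_year + max(b1 - start_year + 2, int(0.78 * n_years))
    return (b1, min(b2, last))


def generate_daily_metric(years, season=SEASON, base_level: float = 50.0,
                          season_amplitude: float = 30.0,
                          event_scale: float = 10.0, ar1_phi: float = 0.7,
                          seed: int | None = None,
                          name: str = "daily_metric") -> DailySeries:
    """Daily fire-danger-like series: smooth seasonal baseline plus
    AR(1) anomalies.

    The deterministic baseline peaks in late summer (like drought/fuel
    dryness indices); ``event_scale`` scales the autocorrelated anomaly
    component (0 gives the pure baseline).  Full calendar years are
    generated so fixed-end windows can reach before the season start.
    """
    years = [int(y) for y in np.atleast_1d(years)]
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    dates = dates[np.isin(dates.year, years)]
    doy = dates.dayofyear.to_numpy(dtype=float)
    ndays_year = np.where(dates.is_leap_year, 366.0, 365.0)
    # baseline peaking around day 225 (mid August)
    baseline = base_level + season_amplitude * np.cos(
        2 * np.pi * (doy - 225.0) / ndays_year)
    rng = np.random.default_rng(seed)
    if event_scale > 0:
        anomalies = event_scale * ar1_series(len(dates), ar1_phi, rng=rng)
    else:
        anomalies = np.zeros(len(dates))
    return DailySeries(name, dates, baseline + anomalies)


def paired_response_from_window(daily: DailySeries, spec: WindowSpec,
                                beta: float = 2.0, noise_sd: float = 0.0,
                                season=SEASON,
                                seed: int | None = None) -> AnnualSeries:
    """Response series driven by one known window statistic of the daily
    record — ground truth for window-recovery tests."""
    summ = seasonal_summary(daily, spec, season)
    rng = np.random.default_rng(seed)
    vals = beta * summ.values + rng.normal(0.0, noise_sd, size=len(summ))
    return AnnualSeries("paired_response", summ.years, vals)
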