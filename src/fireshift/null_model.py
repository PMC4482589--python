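"""Monte-Carlo null model of a constant fire-climate relationship.

The null hypothesis: one regression links climate to ln(area burned) over the
whole record, plus stationary noise.  Under that null, moving-window r2, CE
and standardized slopes still wander through time simply because the response
realizations differ window to window.  Simulating many records from the
fitted global model (observed predictors held fixed, iid Gaussian noise at
the fitted residual sd — or resampled residuals) and re-running the window
sweep on each yields central-95% envelopes; observed trajectories leaving the
envelope are inconsistent with a constant relationship.

The per-realization sweep is vectorized: the design matrix is identical
across realizations, so each window's least-squares projector is computed
once and applied to all simulated responses at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .regression import RegressionModel, fit_ols
from .series import AnnualSeries
from .sweep import enumerate_calibration_windows

__all__ = [
    "NullEnvelope",
    "fit_global_null",
    "simulate_null_realization",
    "batch_sweep_statistics",
    "build_envelope",
    "NullModelEnvelope",
]


@dataclass(frozen=True)
class NullEnvelope:
    """Central-percentile bands of window statistics under the null.

    ``lower``/``upper`` are DataFrames indexed by window center year with one
    column per statistic (``r2``, ``ce``, ``std_beta_<name>``).
    """

    center_years: np.ndarray
    lower: pd.DataFrame
    upper: pd.DataFrame
    n_realizations: int
    seed: int | None
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if not (self.lower.to_numpy() <= self.upper.to_numpy() + 1e-12).all():
            raise ValueError("envelope lower bound exceeds upper bound")

    @property
    def statistics(self) -> list[str]:
        return list(self.lower.columns)

    def contains(self, observed: pd.DataFrame) -> pd.DataFrame:
        """Boolean table: is each observed statistic inside the envelope?

        ``observed`` is a trajectory table as produced by
        :func:`fireshift.sweep.parameter_series` (indexed by center year).
        """
        cols = [c for c in self.statistics if c in observed.columns]
        obs = observed.loc[self.center_years, cols]
        return (obs >= self.lower[cols]) & (obs <= self.upper[cols])

    def coverage(self, observed: pd.DataFrame) -> pd.Series:
        """Fraction of window centers inside the envelope, per statistic."""
        return self.contains(observed).mean(axis=0)

    def exits(self, observed: pd.DataFrame) -> pd.DataFrame:
        """Long table of (center_year, statistic, observed, lower, upper)
        rows where the observed trajectory leaves the envelope."""
        inside = self.contains(observed)
        rows = []
        for stat in inside.columns:
            for cy in inside.index[~inside[stat]]:
                rows.append({
                    "center_year": int(cy), "statistic": stat,
                    "observed": float(observed.loc[cy, stat]),
                    "lower": float(self.lower.loc[cy, stat]),
                    "upper": float(self.upper.loc[cy, stat]),
                })
        return pd.DataFrame(rows,
                            columns=["center_year", "statistic", "observed",
                                     "lower", "upper"])

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready table: center_year, statistic, lower, upper."""
        rows = []
        for stat in self.statistics:
            for cy in self.center_years:
                rows.append({"center_year": int(cy), "statistic": stat,
                             "lower": float(self.lower.loc[cy, stat]),
                             "upper": float(self.upper.loc[cy, stat])})
        return pd.DataFrame(rows)


def fit_global_null(predictors, response: AnnualSeries,
                    min_overlap: int = 50) -> tuple[RegressionModel, float]:
    """Fit the single full-record model; noise sd = residual sd."""
    preds = list(predictors) if isinstance(predictors, (list, tuple)) else [predictors]
    lo = max([p.first_year for p in preds] + [response.first_year])
    hi = min([p.last_year for p in preds] + [response.last_year])
    n = hi - lo + 1
    if n < min_overlap:
        raise ValueError(
            f"global null model requires >= {min_overlap} overlapping years, got {n}"
        )
    model = fit_ols(preds, response, years=np.arange(lo, hi + 1))
    return model, model.resid_sd


def simulate_null_realization(model: RegressionModel, predictors, noise_sd: float,
                              rng: np.random.Generator,
                              years=None, noise: str = "gaussian",
                              residuals: np.ndarray | None = None) -> AnnualSeries:
    """One simulated response: fitted values plus stationary noise.

    Observed predictor values are held fixed; only the response is
    stochastic.  ``noise='gaussian'`` draws iid Normal(0, noise_sd);
    ``noise='resample'`` bootstraps the supplied fitted residuals.
    """
    preds = list(predictors) if isinstance(predictors, (list, tuple)) else [predictors]
    if years is None:
        lo = max(p.first_year for p in preds)
        hi = min(p.last_year for p in preds)
        years = np.arange(lo, hi + 1)
    years = np.asarray(years, dtype=np.int64)
    X = np.column_stack([p.subset(years) for p in preds])
    yhat = model.predict(X)
    if noise == "gaussian":
        eps = rng.normal(0.0, noise_sd, size=len(years))
    elif noise == "resample":
        if residuals is None:
            raise ValueError("noise='resample' requires the fitted residuals")
        eps = rng.choice(residuals, size=len(years), replace=True)
    else:
        raise ValueError(f"unknown noise mechanism {noise!r}")
    return AnnualSeries("null_realization", years, yhat + eps)


def batch_sweep_statistics(X: np.ndarray, Y: np.ndarray, years: np.ndarray,
                           width: int = 21):
    """Window sweep statistics for many responses sharing one design.

    Parameters
    ----------
    X : (n_years, p) predictor matrix (fixed across realizations)
    Y : (n_realizations, n_years) response matrix
    years : (n_years,) consecutive years

    Returns ``(center_years, r2, ce, std_betas)`` where ``r2`` and ``ce`` are
    (n_realizations, n_windows) and ``std_betas`` is
    (n_realizations, n_windows, p).  Standardization uses window-local
    moments, matching the per-window fits.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.size == len(years):
        X = X.reshape(len(years), -1)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    windows = enumerate_calibration_windows(int(years[0]), int(years[-1]), width)
    if len(windows) == 1:
        raise ValueError("window width equals the record span: no validation years")
    nw = len(windows)
    m = Y.shape[0]
    r2 = np.empty((m, nw))
    ce = np.empty((m, nw))
    std_betas = np.empty((m, nw, p))
    for k, w in enumerate(windows):
        i0 = w.start_year - int(years[0])
        i1 = i0 + width
        Xw = X[i0:i1]
        Yw = Y[:, i0:i1]
        Z = np.column_stack([np.ones(width), Xw])
        P = np.linalg.pinv(Z)                       # (p+1, width)
        B = Yw @ P.T                                # (m, p+1)
        fit = B @ Z.T                               # (m, width)
        sse = ((Yw - fit) ** 2).sum(axis=1)
        sst = ((Yw - Yw.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[:, k] = np.clip(1.0 - sse / sst, 0.0, 1.0)
        sx = Xw.std(axis=0, ddof=1)
        sy = Yw.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            std_betas[:, k, :] = B[:, 1:] * sx[None, :] / sy[:, None]
        # validation: all years outside the window
        vmask = np.ones(n, dtype=bool)
        vmask[i0:i1] = False
        Zv = np.column_stack([np.ones(vmask.sum()), X[vmask]])
        pred = B @ Zv.T                             # (m, n_val)
        Yv = Y[:, vmask]
        mse_model = ((Yv - pred) ** 2).mean(axis=1)
        mse_null = ((Yv - Yv.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)
        ce[:, k] = 1.0 - mse_model / mse_null
    centers = np.array([w.center_year for w in windows])
    return centers, r2, ce, std_betas


def build_envelope(predictors, response: AnnualSeries, width: int = 21,
                   n_realizations: int = 10_000, seed: int | None = None,
                   noise: str = "gaussian",
                   percentiles: tuple[float, float] = (2.5, 97.5)) -> NullEnvelope:
    """Central-95% envelopes of window statistics under the constant null.

    Fits the global model, simulates ``n_realizations`` responses (a master
    seed spawns one substream per realization, so results do not depend on
    evaluation order), sweeps each, and takes empirical percentiles per
    window center for r2, CE and each standardized slope.
    """
    if n_realizations < 100:
        warnings.warn(
            f"envelope from only {n_realizations} realizations is unstable",
            stacklevel=2,
        )
    preds = list(predictors) if isinstance(predictors, (list, tuple)) else [predictors]
    model, noise_sd = fit_global_null(preds, response)
    lo = max([p.first_year for p in preds] + [response.first_year])
    hi = min([p.last_year for p in preds] + [response.last_year])
    years = np.arange(lo, hi + 1)
    X = np.column_stack([p.subset(years) for p in preds])
    yhat = model.predict(X)
    resid = response.subset(years) - yhat

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_realizations)
    Y = np.empty((n_realizations, len(years)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if noise == "gaussian":
            Y[i] = yhat + rng.normal(0.0, noise_sd, size=len(years))
        elif noise == "resample":
            Y[i] = yhat + rng.choice(resid, size=len(years), replace=True)
        else:
            raise ValueError(f"unknown noise mechanism {noise!r}")

    centers, r2, ce, std_betas = batch_sweep_statistics(X, Y, years, width)
    names = [p.name for p in preds]
    stats = {"r2": r2, "ce": ce}
    for j, name in enumerate(names):
        stats[f"std_beta_{name}"] = std_betas[:, :, j]
    lo_q, hi_q = percentiles
    lower = pd.DataFrame(
        {k: np.percentile(v, lo_q, axis=0) for k, v in stats.items()},
        index=pd.Index(centers, name="center_year"))
    upper = pd.DataFrame(
        {k: np.percentile(v, hi_q, axis=0) for k, v in stats.items()},
        index=pd.Index(centers, name="center_year"))
    return NullEnvelope(center_years=centers, lower=lower, upper=upper,
                        n_realizations=n_realizations, seed=seed,
                        percentiles=percentiles)


class NullModelEnvelope(BaseEstimator):
    """Estimator-style interface to the constant-relationship null envelope.

    ``fit(X, y)`` (year-indexed DataFrame / Series) fits the global model and
    builds the envelope; ``envelope_``, ``global_model_`` and ``noise_sd_``
    are then available, and :meth:`coverage`/:meth:`exits` compare an
    observed trajectory table against the bands.
    """

    def __init__(self, width: int = 21, n_realizations: int = 10_000,
                 seed: int | None = None, noise: str = "gaussian",
                 percentiles: tuple[float, float] = (2.5, 97.5)):
        self.width = width
        self.n_realizations = n_realizations
        self.seed = seed
        self.noise = noise
        self.percentiles = percentiles

    def fit(self, X: pd.DataFrame, y):
        preds = [AnnualSeries(str(c), np.asarray(X.index, dtype=np.int64),
                              X[c].to_numpy(dtype=float)) for c in X.columns]
        y = pd.Series(np.asarray(y, dtype=float), index=X.index) \
            if not isinstance(y, pd.Series) else y
        resp = AnnualSeries(str(y.name or "response"),
                            np.asarray(y.index, dtype=np.int64),
                            y.to_numpy(dtype=float))
        self.global_model_, self.noise_sd_ = fit_global_null(preds, resp)
        self.envelope_ = build_envelope(
            preds, resp, width=self.width, n_realizations=self.n_realizations,
            seed=self.seed, noise=self.noise, percentiles=self.percentiles)
        return self

    def coverage(self, observed: pd.DataFrame) -> pd.Series:
        return self.envelope_.coverage(observed)

    def exits(self, observed: pd.DataFrame) -> pd.DataFrame:
        return self.envelope_.exits(observed)
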