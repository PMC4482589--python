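"""Core regression statistics for fire-climate modeling.

The response variable is the natural log of annual area burned (zeros are
replaced by a small offset, 10 ha by default, before transforming).  Models
are ordinary least squares with one to three climate predictors; skill
outside the calibration span is measured with the coefficient of efficiency

    CE = 1 - sum (y_t - yhat_t)^2 / sum (y_t - ybar_v)^2,

where ybar_v is the validation-period mean of the observations.  CE ranges
over (-inf, 1]; CE > 0 means the regression beats the climatological-mean
null, CE < 0 signals that the relationship fitted in the calibration span
does not transfer to the validation span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .series import AnnualSeries, common_span

__all__ = [
    "RegressionModel",
    "SkillResult",
    "log_transform_area",
    "fit_ols",
    "variance_inflation_factors",
    "lilliefors_normality",
    "coefficient_of_efficiency",
]


@dataclass(frozen=True)
class RegressionModel:
    """A fitted OLS model with 1-3 predictors.

    ``std_betas`` are the slopes after z-scoring each predictor and the
    response over the fitted years: the change in ln(area burned), in
    standard deviations, per standard-deviation change in the metric.
    """

    beta0: float
    betas: np.ndarray
    std_betas: np.ndarray
    r2: float
    r2_adj: float | None
    resid_sd: float
    n_obs: int
    predictor_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.betas):
            if X.shape[0] == len(self.betas):  # tolerate (p, n) orientation
                X = X.T
            else:
                raise ValueError(
                    f"X has {X.shape[1]} columns, model has {len(self.betas)} predictors"
                )
        return self.beta0 + X @ self.betas

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "betas": list(map(float, self.betas)),
            "std_betas": list(map(float, self.std_betas)),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "resid_sd": self.resid_sd,
            "n_obs": self.n_obs,
            "predictor_names": list(self.predictor_names),
        }


@dataclass(frozen=True)
class SkillResult:
    """Coefficient-of-efficiency cross-validation skill."""

    ce: float
    mse_model: float
    mse_null: float
    n_validation: int


def log_transform_area(
    area_ha: AnnualSeries, zero_offset_ha: float = 10.0
) -> AnnualSeries:
    """Natural log of annual area burned; zeros get ``ln(zero_offset_ha)``.

    The offset is applied only to exact zeros (a handful of zero-burn years
    at most), not added globally.
    """
    v = area_ha.values
    if np.any(v < 0):
        bad = area_ha.years[v < 0]
        raise ValueError(f"negative area burned in year(s) {bad.tolist()}")
    out = np.where(v == 0.0, float(zero_offset_ha), v)
    return AnnualSeries(f"ln({area_ha.name})", area_ha.years, np.log(out))


def _as_design(predictors, years=None):
    """Normalize predictors to (X, y years, names)."""
    if isinstance(predictors, AnnualSeries):
        predictors = [predictors]
    names = tuple(p.name for p in predictors)
    if years is None:
        lo, hi = common_span(*predictors)
        years = np.arange(lo, hi + 1)
    years = np.asarray(years, dtype=np.int64)
    X = np.column_stack([p.subset(years) for p in predictors])
    return X, years, names


def _ols_core(X: np.ndarray, y: np.ndarray):
    """Plain least squares with an intercept; returns (coefs, sse, rank)."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    coefs, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coefs
    return coefs, float(resid @ resid), rank


def fit_ols(predictors, response: AnnualSeries | np.ndarray, years=None,
            predictor_names=None) -> RegressionModel:
    """Ordinary least squares of the response on 1-3 predictors.

    Accepts either :class:`AnnualSeries` objects (aligned on ``years`` or on
    their common span) or raw arrays.  Standardized slopes are refit on
    z-scored columns over the same observations.
    """
    if isinstance(predictors, np.ndarray):
        X = np.atleast_2d(predictors.astype(float))
        if X.shape[0] == 1 and X.size > 1 and X.shape[1] != 1:
            X = X.T
        y = np.asarray(response, dtype=float)
        names = tuple(predictor_names or
                      [f"x{i + 1}" for i in range(X.shape[1])])
    else:
        X, yrs, names = _as_design(predictors, years)
        y = response.subset(yrs) if isinstance(response, AnnualSeries) else np.asarray(response, float)
    n, p = X.shape
    if not 1 <= p <= 3:
        raise ValueError(f"need 1-3 predictors, got {p}")
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} observations for {p} predictors, got {n}")

    coefs, sse, rank = _ols_core(X, y)
    if rank < p + 1:
        corr = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(
            "rank-deficient design; collinear predictors: "
            + (", ".join(pairs) if pairs else str(names))
        )
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    r2_adj = None
    if p >= 2:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    resid_sd = float(np.sqrt(sse / (n - p - 1)))

    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if sy > 0 and np.all(sx > 0):
        std_betas = coefs[1:] * sx / sy
    else:
        std_betas = np.zeros(p)
    return RegressionModel(
        beta0=float(coefs[0]), betas=coefs[1:].copy(), std_betas=std_betas,
        r2=float(r2), r2_adj=None if r2_adj is None else float(r2_adj),
        resid_sd=resid_sd, n_obs=n, predictor_names=names,
    )


def variance_inflation_factors(predictors, years=None):
    """VIF_j = 1/(1 - R^2_j) from regressing predictor j on the others.

    Returns ``(vifs, flagged)`` where ``flagged`` is True when any VIF is at
    or above 10, the conventional multicollinearity alarm. Perfectly
    collinear predictors get ``inf``.
    """
    if isinstance(predictors, np.ndarray):
        X = predictors.astype(float)
        names = [f"x{i+1}" for i in range(X.shape[1])]
    else:
        X, _, names = _as_design(predictors, years)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF requires at least two predictors")
    vifs = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        coefs, sse, rank = _ols_core(others, X[:, j])
        sst = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if sst == 0:
            vifs[j] = np.inf
            continue
        r2j = 1.0 - sse / sst
        vifs[j] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return vifs, bool(np.max(vifs) >= 10.0)


# ---------------------------------------------------------------------------
# Lilliefors normality test with a Monte-Carlo null distribution
# ---------------------------------------------------------------------------

_LF_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    return float(_lilliefors_stat_batch(x[None, :])[0])


def _lilliefors_stat_batch(X: np.ndarray) -> np.ndarray:
    """KS distance to a normal with estimated mean/sd, per row."""
    n = X.shape[1]
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def _lilliefors_null_table(n: int, n_sims: int, seed: int) -> np.ndarray:
    key = (n, n_sims, seed)
    if key not in _LF_TABLE_CACHE:
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_sims, n))
        _LF_TABLE_CACHE[key] = np.sort(_lilliefors_stat_batch(sims))
    return _LF_TABLE_CACHE[key]


def lilliefors_normality(values, alpha: float = 0.05, n_sims: int = 5000,
                         seed: int = 20_0905):
    """Lilliefors goodness-of-fit test for normality.

    The statistic is the KS distance between the empirical CDF and a normal
    CDF with estimated mean and sd; because parameters are estimated, the
    null distribution is simulated (``n_sims`` standard-normal samples of the
    same size, fixed seed; distribution-free, so the table is cached per n).
    Returns ``(statistic, p_value, passed)`` with ``passed = p >= alpha``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("lilliefors test requires a 1-d sample with n >= 10")
    if x.std(ddof=1) == 0:
        raise ValueError("constant series: normality test undefined (sd = 0)")
    d = _lilliefors_stat(x)
    table = _lilliefors_null_table(len(x), n_sims, seed)
    n_ge = len(table) - np.searchsorted(table, d, side="left")
    p = (1.0 + n_ge) / (1.0 + n_sims)
    return d, float(p), bool(p >= alpha)


def coefficient_of_efficiency(observed, predicted) -> SkillResult:
    """CE = 1 - MSE(model) / MSE(validation-period mean).

    CE = 1 for perfect predictions, 0 when the model is no better than the
    validation-period mean, and negative when it is worse.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d arrays")
    if len(y) < 2:
        raise ValueError("need at least 2 validation values")
    ybar = y.mean()
    mse_null = float(((y - ybar) ** 2).mean())
    if mse_null == 0.0:
        raise ValueError("observed validation values have zero variance")
    mse_model = float(((y - yhat) ** 2).mean())
    return SkillResult(ce=1.0 - mse_model / mse_null, mse_model=mse_model,
                       mse_null=mse_null, n_validation=len(y))
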