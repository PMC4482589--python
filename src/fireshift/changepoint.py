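"""Changepoint detection on the cumulative log area-burned series.

Periods of distinct mean fire activity show up as slope breaks in the
cumulative sum of annual ln(area burned): the slope of each linear segment
of the cumulative series equals the mean annual ln-area within it.  The
detector fits a piecewise-linear function with ``n_breakpoints`` free knots
at integer year boundaries, minimizing total squared error, and reports the
break years plus each break's share of the SSE improvement (so a weak break
is identifiable when more breaks are requested than the record supports).

The search is exact: every feasible breakpoint combination (minimum segment
length enforced) is evaluated.  For the continuous (default) fit the normal
equations for each combination are assembled in closed form from prefix sums
and solved in a single batched call, which keeps the exhaustive search fast
even for century-long records with three breaks.  A discontinuous variant
(independent line per segment) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from .series import AnnualSeries

__all__ = [
    "ChangepointResult",
    "cumulative_series",
    "piecewise_fit",
    "ChangepointDetector",
]


@dataclass(frozen=True)
class ChangepointResult:
    """Breakpoints of a piecewise-linear fit to a cumulative series.

    A breakpoint year labels the FIRST year of the new segment (a 1943 break
    means the second period is 1943 onward).  ``segment_slopes`` are the
    per-segment slopes of the cumulative fit, i.e. the segment-mean annual
    values.  ``degenerate`` flags fits whose SSE improvement over a single
    line is negligible (breakpoint positions are then arbitrary).
    """

    breakpoint_years: tuple[int, ...]
    segment_slopes: tuple[float, ...]
    sse: float
    n_breakpoints: int
    sse_no_breaks: float
    improvement_share: tuple[float, ...]
    degenerate: bool
    continuity: bool

    def to_dict(self) -> dict:
        return {
            "breakpoint_years": list(self.breakpoint_years),
            "segment_slopes": list(self.segment_slopes),
            "sse": self.sse,
            "n_breakpoints": self.n_breakpoints,
            "sse_no_breaks": self.sse_no_breaks,
            "improvement_share": list(self.improvement_share),
            "degenerate": self.degenerate,
            "continuity": self.continuity,
        }


def cumulative_series(ln_area: AnnualSeries) -> AnnualSeries:
    """Running sum of the annual series (first value = first input)."""
    return AnnualSeries(f"cumulative({ln_area.name})", ln_area.years,
                        np.cumsum(ln_area.values))


# ---------------------------------------------------------------------------
# Continuous piecewise-linear fit: batched closed-form normal equations
# ---------------------------------------------------------------------------

def _feasible_breaks(n: int, k: int, min_segment: int) -> np.ndarray:
    """All index combinations (break = first index of new segment)."""
    lo, hi = min_segment, n - min_segment  # inclusive candidate range
    cands = range(lo, hi + 1)
    combos = [c for c in combinations(cands, k)
              if all(c[i + 1] - c[i] >= min_segment for i in range(k - 1))]
    if not combos:
        raise ValueError(
            f"no feasible breakpoint placement: n={n}, k={k}, "
            f"min_segment={min_segment}"
        )
    return np.array(combos, dtype=np.int64)


def _hinge_knots(breaks: np.ndarray) -> np.ndarray:
    # knot between the last year of the old segment and the first of the new
    return breaks - 0.5


def _continuous_sse_batch(y: np.ndarray, combos: np.ndarray):
    """SSE of the continuous piecewise-linear fit for every break combo.

    Design per combo: [1, t, (t-k_1)+, ..., (t-k_K)+] with t = 0..n-1 and
    knots k_j = b_j - 0.5.  All Gram/moment entries are closed forms in the
    suffix sums of 1, t, t^2, y and t*y, so the (m+2)x(m+2) systems are
    assembled and solved for all combos at once.

    Returns (sse, coefs) with coefs of shape (n_combos, k+2).
    """
    n = len(y)
    k = combos.shape[1]
    t = np.arange(n, dtype=float)
    # suffix sums: S*(b) = sum over t >= b
    def suffix(a):
        out = np.zeros(n + 1)
        out[:n] = np.cumsum(a[::-1])[::-1]
        return out

    S0 = suffix(np.ones(n))
    S1 = suffix(t)
    S2 = suffix(t * t)
    T0 = suffix(y)
    T1 = suffix(t * y)

    m = k + 2
    nc = combos.shape[0]
    knots = _hinge_knots(combos.astype(float))          # (nc, k)
    b = combos                                           # integer start index

    G = np.empty((nc, m, m))
    r = np.empty((nc, m))
    # constant and linear columns
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = S1[0]
    G[:, 1, 1] = S2[0]
    r[:, 0] = T0[0]
    r[:, 1] = T1[0]
    for j in range(k):
        bj = b[:, j]
        kj = knots[:, j]
        g0 = S1[bj] - kj * S0[bj]                        # <1, h_j>
        g1 = S2[bj] - kj * S1[bj]                        # <t, h_j>
        G[:, 0, 2 + j] = G[:, 2 + j, 0] = g0
        G[:, 1, 2 + j] = G[:, 2 + j, 1] = g1
        r[:, 2 + j] = T1[bj] - kj * T0[bj]               # <h_j, y>
        for i in range(j + 1):
            bi, ki = b[:, i], knots[:, i]
            # hinge i is nonzero wherever hinge j is (b_i <= b_j)
            gij = S2[bj] - (ki + kj) * S1[bj] + ki * kj * S0[bj]
            G[:, 2 + i, 2 + j] = G[:, 2 + j, 2 + i] = gij
    coefs = np.linalg.solve(G, r[..., None])[..., 0]
    yty = float(y @ y)
    sse = yty - np.einsum("ij,ij->i", coefs, r)
    return np.maximum(sse, 0.0), coefs


def _segment_slopes_continuous(coefs: np.ndarray) -> np.ndarray:
    """Slopes per segment: base slope plus cumulative hinge coefficients."""
    return coefs[1] + np.concatenate([[0.0], np.cumsum(coefs[2:])])


def _discontinuous_fit(y: np.ndarray, k: int, min_segment: int):
    """Exact DP: independent least-squares line per segment."""
    n = len(y)
    t = np.arange(n, dtype=float)
    # segment SSE table via prefix sums
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    ct = np.concatenate([[0.0], np.cumsum(t)])
    ct2 = np.concatenate([[0.0], np.cumsum(t * t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_sse(a, bnd):  # years a..bnd-1
        m = c1[bnd] - c1[a]
        st, st2 = ct[bnd] - ct[a], ct2[bnd] - ct2[a]
        sy, sty = cy[bnd] - cy[a], cty[bnd] - cty[a]
        sy2 = cy2[bnd] - cy2[a]
        det = m * st2 - st * st
        if det <= 0:
            return sy2 - sy * sy / m if m > 0 else 0.0
        slope = (m * sty - st * sy) / det
        icept = (sy - slope * st) / m
        return max(sy2 - icept * sy - slope * sty, 0.0)

    INF = np.inf
    # dp[j][i]: best SSE splitting y[:i] into j segments
    dp = np.full((k + 2, n + 1), INF)
    arg = np.zeros((k + 2, n + 1), dtype=np.int64)
    for i in range(min_segment, n + 1):
        dp[1][i] = seg_sse(0, i)
    for j in range(2, k + 2):
        for i in range(j * min_segment, n + 1):
            best, besta = INF, -1
            for a in range((j - 1) * min_segment, i - min_segment + 1):
                v = dp[j - 1][a] + seg_sse(a, i)
                if v < best:
                    best, besta = v, a
            dp[j][i], arg[j][i] = best, besta
    breaks = []
    i = n
    for j in range(k + 1, 1, -1):
        i = int(arg[j][i])
        breaks.append(i)
    breaks = sorted(breaks)
    # slopes per segment
    bounds = [0] + breaks + [n]
    slopes = []
    for a, bnd in zip(bounds[:-1], bounds[1:]):
        tt, yy = t[a:bnd], y[a:bnd]
        slopes.append(float(np.polyfit(tt, yy, 1)[0]) if bnd - a > 1 else 0.0)
    return np.array(breaks), float(dp[k + 1][n]), np.array(slopes)


def piecewise_fit(cum: AnnualSeries, n_breakpoints: int = 3,
                  continuity: bool = True, min_segment: int = 5,
                  degenerate_tol: float = 1e-9) -> ChangepointResult:
    """Globally optimal piecewise-linear fit to a cumulative series.

    Breakpoints are searched over integer year boundaries with at least
    ``min_segment`` years per segment.  With ``continuity=True`` (default)
    the fitted function is a linear spline — the natural model for a
    cumulative series, which is continuous by construction.
    """
    y = cum.values.astype(float)
    n = len(y)
    k = int(n_breakpoints)
    if k < 1:
        raise ValueError("n_breakpoints must be >= 1")
    if n < 5 * (k + 1):
        raise ValueError(
            f"record of {n} yr too short for {k} breakpoints "
            f"(need >= {5 * (k + 1)})"
        )
    if min_segment * (k + 1) > n:
        raise ValueError("infeasible segment lengths")

    t = np.arange(n, dtype=float)
    line = np.polyfit(t, y, 1)
    sse0 = float(((y - np.polyval(line, t)) ** 2).sum())

    if continuity:
        combos = _feasible_breaks(n, k, min_segment)
        sse_all, coefs_all = _continuous_sse_batch(y, combos)
        best = int(np.argmin(sse_all))
        breaks_idx = combos[best]
        sse = float(sse_all[best])
        slopes = _segment_slopes_continuous(coefs_all[best])
        # per-break improvement: SSE gain lost when that break is removed
        improvements = []
        for drop in range(k):
            kept = np.delete(breaks_idx, drop)[None, :]
            if kept.shape[1] == 0:
                sse_wo = sse0
            else:
                sse_wo = float(_continuous_sse_batch(y, kept)[0][0])
            improvements.append(max(sse_wo - sse, 0.0))
    else:
        breaks_idx, sse, slopes = _discontinuous_fit(y, k, min_segment)
        improvements = []
        for drop in range(k):
            kept = np.delete(breaks_idx, drop)
            if len(kept) == 0:
                sse_wo = sse0
            else:
                sse_wo = _dp_sse_given_breaks(y, kept, min_segment)
            improvements.append(max(sse_wo - sse, 0.0))

    total_gain = sse0 - sse
    degenerate = total_gain <= degenerate_tol * max(sse0, 1.0)
    imp = np.array(improvements)
    shares = imp / imp.sum() if imp.sum() > 0 else np.zeros(k)
    years = tuple(int(cum.years[i]) for i in np.sort(np.asarray(breaks_idx)))
    return ChangepointResult(
        breakpoint_years=years,
        segment_slopes=tuple(float(s) for s in slopes),
        sse=float(sse), n_breakpoints=k, sse_no_breaks=sse0,
        improvement_share=tuple(float(s) for s in shares),
        degenerate=bool(degenerate), continuity=continuity,
    )


def _dp_sse_given_breaks(y, breaks, min_segment):
    """SSE of independent per-segment lines at fixed breakpoints."""
    n = len(y)
    t = np.arange(n, dtype=float)
    bounds = [0] + list(np.sort(breaks)) + [n]
    sse = 0.0
    for a, bnd in zip(bounds[:-1], bounds[1:]):
        tt, yy = t[a:bnd], y[a:bnd]
        if bnd - a > 1:
            coef = np.polyfit(tt, yy, 1)
            sse += float(((yy - np.polyval(coef, tt)) ** 2).sum())
    return sse


class ChangepointDetector(BaseEstimator):
    """Estimator interface: ``fit(ln_area)`` finds mean-shift years.

    Takes the ANNUAL ln-area series (cumulation happens internally) and
    exposes ``breakpoint_years_``, ``segment_slopes_`` (segment-mean annual
    ln-area), ``result_`` and ``periods_`` (list of (start, end) year pairs).
    """

    def __init__(self, n_breakpoints: int = 3, continuity: bool = True,
                 min_segment: int = 5):
        self.n_breakpoints = n_breakpoints
        self.continuity = continuity
        self.min_segment = min_segment

    def fit(self, ln_area: AnnualSeries, y=None):
        cum = cumulative_series(ln_area)
        self.result_ = piecewise_fit(
            cum, n_breakpoints=self.n_breakpoints,
            continuity=self.continuity, min_segment=self.min_segment)
        self.breakpoint_years_ = list(self.result_.breakpoint_years)
        self.segment_slopes_ = list(self.result_.segment_slopes)
        edges = ([ln_area.first_year] + self.breakpoint_years_
                 + [ln_area.last_year + 1])
        self.periods_ = [(edges[i], edges[i + 1] - 1)
                         for i in range(len(edges) - 1)]
        return self
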