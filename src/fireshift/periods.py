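"""Among-period comparison of climate metrics.

Once changepoints split the record into discrete fire-activity periods, each
climate metric is tested for differences among periods with a Kruskal-Wallis
rank ANOVA.  Because annual climate series can be autocorrelated, the
analytic chi-square p-value is replaced by a circular block-bootstrap null
whenever any lag-1..5 autocorrelation is significant: the chronological
series is resampled in blocks (block length = largest significant lag),
reassembled to full length, and split at the SAME period boundaries, so the
null preserves serial dependence while destroying the period-mean structure.
Significant omnibus tests are followed by Tukey HSD pairwise comparisons on
the rank-transformed values, summarized as a compact letter display (periods
sharing a letter are statistically indistinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .series import AnnualSeries

__all__ = [
    "PeriodComparison",
    "significant_autocorrelation_lag",
    "kruskal_wallis",
    "block_bootstrap_pvalue",
    "tukey_grouping",
    "compare_periods",
]


@dataclass(frozen=True)
class PeriodComparison:
    """Full among-period test result for one metric."""

    metric_name: str
    period_labels: tuple[str, ...]
    chi2: float
    df: int
    p_analytic: float
    largest_sig_lag: int
    block_length: int
    p_bootstrap: float | None
    n_boot: int
    significant: bool
    letters: tuple[str, ...] | None

    @property
    def p_value(self) -> float:
        """The p-value actually used for the significance call."""
        return self.p_bootstrap if self.p_bootstrap is not None else self.p_analytic

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "periods": list(self.period_labels),
            "chi2": self.chi2, "df": self.df,
            "p_analytic": self.p_analytic,
            "largest_sig_lag": self.largest_sig_lag,
            "block_length": self.block_length,
            "p_bootstrap": self.p_bootstrap, "n_boot": self.n_boot,
            "significant": self.significant,
            "letters": None if self.letters is None else list(self.letters),
        }


def significant_autocorrelation_lag(values, max_lag: int = 5) -> int:
    """Largest lag in 1..max_lag with |r_k| > 1.96/sqrt(n); 0 if none."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("autocorrelation screen requires n >= 20")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    crit = 1.96 / np.sqrt(n)
    largest = 0
    for k in range(1, max_lag + 1):
        rk = float(xc[:-k] @ xc[k:]) / denom
        if abs(rk) > crit:
            largest = k
    return largest


def _kw_statistic(ranks: np.ndarray, group_slices: list[slice]) -> np.ndarray:
    """Tie-corrected Kruskal-Wallis H via the rank-ANOVA identity.

    ``ranks`` is (n_sets, n) of midranks per row; H = (N-1) * SSB / SST of
    the ranks, which equals the classical tie-corrected statistic and is 0
    when all pooled values are identical.
    """
    n = ranks.shape[1]
    grand = ranks.mean(axis=1, keepdims=True)
    sst = ((ranks - grand) ** 2).sum(axis=1)
    ssb = np.zeros(ranks.shape[0])
    for sl in group_slices:
        nj = sl.stop - sl.start
        gmean = ranks[:, sl].mean(axis=1)
        ssb += nj * (gmean - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (n - 1) * ssb / sst
    return np.where(sst > 0, h, 0.0)


def _pooled_ranks(groups):
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    slices, start = [], 0
    for s in sizes:
        slices.append(slice(start, start + s))
        start += s
    return pooled, slices


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis test; returns (chi2, df, p_analytic).

    ``p_analytic`` is the chi-square tail probability with groups-1 degrees
    of freedom.  Identical groups give chi2 = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group must have n >= 3")
    pooled, slices = _pooled_ranks(groups)
    ranks = stats.rankdata(pooled)[None, :]
    h = float(_kw_statistic(ranks, slices)[0])
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
    return h, df, p


def _circular_block_indices(n: int, block_length: int, n_boot: int,
                            rng: np.random.Generator) -> np.ndarray:
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n, size=(n_boot, n_blocks))
    offsets = np.arange(block_length)
    idx = (starts[:, :, None] + offsets[None, None, :]) % n
    return idx.reshape(n_boot, n_blocks * block_length)[:, :n]


def block_bootstrap_pvalue(values, period_ids, block_length: int,
                           n_boot: int = 5000, seed: int | None = None) -> float:
    """Empirical p-value of the Kruskal-Wallis statistic under a
    circular block-bootstrap null.

    The full chronological series is resampled in circular blocks of
    ``block_length`` consecutive years, reassembled to the original length,
    and split at the SAME period boundaries; the p-value is
    ``(1 + #{H* >= H_obs}) / (1 + n_boot)``.
    """
    x = np.asarray(values, dtype=float)
    ids = np.asarray(period_ids)
    if len(x) != len(ids):
        raise ValueError("values and period assignment must align")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    # periods must be contiguous runs in chronological order
    uniq = []
    for v in ids:
        if not uniq or uniq[-1] != v:
            uniq.append(v)
    if len(uniq) != len(set(uniq)):
        raise ValueError("periods must be contiguous in time")
    slices = []
    for v in uniq:
        pos = np.flatnonzero(ids == v)
        slices.append(slice(int(pos[0]), int(pos[-1]) + 1))
    shortest = min(sl.stop - sl.start for sl in slices)
    if any(sl.stop - sl.start < 3 for sl in slices):
        raise ValueError("every period must have n >= 3")
    if block_length > shortest:
        raise ValueError(
            f"block_length {block_length} exceeds shortest period ({shortest} yr)"
        )
    n = len(x)
    ranks_obs = stats.rankdata(x)[None, :]
    h_obs = float(_kw_statistic(ranks_obs, slices)[0])

    rng = np.random.default_rng(seed)
    idx = _circular_block_indices(n, block_length, n_boot, rng)
    resampled = x[idx]
    ranks = stats.rankdata(resampled, axis=1)
    h_star = _kw_statistic(ranks, slices)
    return float((1.0 + np.sum(h_star >= h_obs - 1e-12)) / (1.0 + n_boot))


def tukey_grouping(groups, alpha: float = 0.05, on: str = "ranks",
                   labels=None) -> tuple[str, ...]:
    """Compact letter display from pairwise Tukey HSD comparisons.

    Pairwise tests use the studentized-range HSD criterion on the pooled
    rank-transformed values by default (``on='raw'`` uses the raw values).
    Groups that are not significantly different share a letter; letters are
    assigned to the maximal cliques of the non-significance graph, ordered
    by group mean.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group must have n >= 3")
    if on == "ranks":
        pooled, slices = _pooled_ranks(groups)
        ranked = stats.rankdata(pooled)
        work = [ranked[sl] for sl in slices]
    elif on == "raw":
        work = groups
    else:
        raise ValueError(f"unknown mode {on!r}")
    res = stats.tukey_hsd(*work)
    k = len(groups)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if res.pvalue[i, j] >= alpha:
                g.add_edge(i, j)
    cliques = list(nx.find_cliques(g))
    means = [float(np.mean(w)) for w in work]
    cliques.sort(key=lambda c: min(means[i] for i in c))
    letters: list[list[str]] = [[] for _ in range(k)]
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_idx)
        for i in clique:
            letters[i].append(letter)
    return tuple("".join(sorted(ls)) for ls in letters)


def split_by_breakpoints(series: AnnualSeries, breakpoints) -> list[np.ndarray]:
    """Split a series' values into contiguous periods at the given break
    years (a break year starts the new period)."""
    bps = sorted(int(b) for b in breakpoints)
    edges = [series.first_year] + bps + [series.last_year + 1]
    if any(edges[i] >= edges[i + 1] for i in range(len(edges) - 1)):
        raise ValueError("breakpoints must be interior to the series span")
    return [series.values[(series.years >= a) & (series.years < b)]
            for a, b in zip(edges[:-1], edges[1:])]


def compare_periods(metric: AnnualSeries, breakpoints, alpha: float = 0.05,
                    max_lag: int = 5, n_boot: int = 5000,
                    seed: int | None = None,
                    min_period: int = 10,
                    force_bootstrap: bool = False) -> PeriodComparison:
    """Full among-period test for one metric.

    Screens lag 1-5 autocorrelation; uses the analytic chi-square p-value
    when no lag is significant, otherwise the circular block-bootstrap
    p-value with block length equal to the largest significant lag.  If the
    chosen p-value is below ``alpha``, Tukey HSD letters are attached.
    """
    groups = split_by_breakpoints(metric, breakpoints)
    if len(groups) < 2:
        raise ValueError("breakpoints must define at least two periods")
    if any(len(g) < min_period for g in groups):
        raise ValueError(f"every period must span >= {min_period} yr")
    lag = significant_autocorrelation_lag(metric.values, max_lag=max_lag)
    chi2, df, p_analytic = kruskal_wallis(groups)
    block_length = max(lag, 1)
    p_boot = None
    if lag >= 1 or force_bootstrap:
        ids = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
        p_boot = block_bootstrap_pvalue(metric.values, ids, block_length,
                                        n_boot=n_boot, seed=seed)
    p_used = p_boot if p_boot is not None else p_analytic
    significant = bool(p_used < alpha)
    letters = tukey_grouping(groups, alpha=alpha) if significant else None
    bps = sorted(int(b) for b in breakpoints)
    edges = [metric.first_year] + bps + [metric.last_year]
    labels = []
    starts = [metric.first_year] + bps
    ends = [b - 1 for b in bps] + [metric.last_year]
    labels = tuple(f"{a}-{b}" for a, b in zip(starts, ends))
    return PeriodComparison(
        metric_name=metric.name, period_labels=labels, chi2=chi2, df=df,
        p_analytic=p_analytic, largest_sig_lag=lag, block_length=block_length,
        p_bootstrap=p_boot, n_boot=n_boot if p_boot is not None else 0,
        significant=significant, letters=letters,
    )
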