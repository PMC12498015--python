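"""Survival and screening statistics.

Self-contained implementations of every statistic the screens rely on:
the product-limit (Kaplan-Meier) survival estimator, horizon survival
lookup, the log-rank (Mantel-Cox) test, observed/expected hazard ratios,
quartile binning, the Mann-Whitney U test, Pearson correlation, the
hypergeometric enrichment tail and Benjamini-Hochberg FDR adjustment.

External survival libraries are used only as independent oracles in the
test suite, never here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, isfinite

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "HazardRatioResult",
    "QuartileAssignment",
    "ZeroVarianceError",
    "km_fit",
    "survival_at",
    "logrank",
    "hazard_ratio_oe",
    "quartile_bins",
    "median_split",
    "mann_whitney",
    "pearson_r",
    "bh_fdr",
    "hypergeom_enrichment",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")  # Q1 = highest expression


class ZeroVarianceError(ValueError):
    """Raised when a statistic is undefined because a sample is constant."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate of a survival function.

    Attributes
    ----------
    event_times : ndarray
        Ascending distinct times at which at least one death occurred.
    at_risk : ndarray
        Number of subjects at risk just before each event time.
    deaths : ndarray
        Number of deaths at each event time.
    survival : ndarray
        Product-limit estimate evaluated at each event time.
    n_total : int
        Number of subjects the curve was fitted on.
    max_followup : float
        Largest observed time (event or censoring).
    no_events : bool
        True when the input contained no events; the curve is then
        identically one.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    n_total: int
    max_followup: float
    no_events: bool = False


def _as_surv_arrays(times, status):
    t = np.asarray(times, dtype=float)
    s = np.asarray(status)
    if t.ndim != 1 or s.shape != t.shape:
        raise ValueError("times and status must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("all times must be finite and > 0")
    s = s.astype(bool)
    return t, s


def km_fit(times, status) -> SurvivalCurve:
    """Fit the product-limit estimator.

    ``status`` is truthy for an event (death) and falsy for censoring.
    Ties at one time are handled with the standard convention: deaths are
    processed before censorings, so a subject censored at an event time is
    still in the risk set for that event.
    """
    t, s = _as_surv_arrays(times, status)
    n = t.size
    if not s.any():
        warnings.warn("no events observed; survival curve is identically 1",
                      stacklevel=2)
        empty = np.empty(0)
        return SurvivalCurve(empty, empty.astype(int), empty.astype(int),
                             empty, n, float(t.max()), no_events=True)
    event_times = np.unique(t[s])
    # at risk just before t_i: everyone with observed time >= t_i
    order = np.sort(t)
    at_risk = n - np.searchsorted(order, event_times, side="left")
    death_sorted = np.sort(t[s])
    deaths = (np.searchsorted(death_sorted, event_times, side="right")
              - np.searchsorted(death_sorted, event_times, side="left"))
    survival = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(event_times, at_risk.astype(int),
                         deaths.astype(int), survival, n, float(t.max()))


def survival_at(curve: SurvivalCurve, horizon: float) -> tuple[float, bool]:
    """Evaluate the step-function survival estimate at ``horizon``.

    Returns ``(value, defined)``.  The value is the right-continuous step
    function at the horizon; when the horizon exceeds the curve's maximum
    follow-up the last estimate is carried forward and ``defined`` is
    False.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    defined = horizon <= curve.max_followup
    if curve.no_events or curve.event_times.size == 0:
        return 1.0, defined
    idx = int(np.searchsorted(curve.event_times, horizon, side="right"))
    value = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    return value, defined


# ---------------------------------------------------------------------------
# Log-rank test and O/E hazard ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple
    observed: np.ndarray    # per-group observed deaths O_g
    expected: np.ndarray    # per-group expected deaths E_g


@dataclass(frozen=True)
class HazardRatioResult:
    """Observed/expected (Mantel-Haenszel style) hazard ratio.

    ``hr = (O_a/E_a) / (O_b/E_b)``; the standard error of log(hr) is
    ``sqrt(1/E_a + 1/E_b)``.  ``defined`` is False when an expectation is
    zero or an observed count is zero (hr would be 0 or infinite); such
    results are excluded from downstream filters.
    """

    hr: float
    log_hr_se: float
    group_a: str
    group_b: str
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    defined: bool


def _logrank_tables(group_ids, times, status, n_groups):
    """Per-event-time at-risk and death counts for each group.

    Returns (event_times, n_at_risk[g, i], deaths[g, i]).
    """
    t, s = _as_surv_arrays(times, status)
    g = np.asarray(group_ids)
    event_times = np.unique(t[s])
    n_risk = np.empty((n_groups, event_times.size))
    d = np.empty((n_groups, event_times.size))
    for gi in range(n_groups):
        tg = np.sort(t[g == gi])
        dg = np.sort(t[(g == gi) & s])
        n_risk[gi] = tg.size - np.searchsorted(tg, event_times, side="left")
        d[gi] = (np.searchsorted(dg, event_times, side="right")
                 - np.searchsorted(dg, event_times, side="left"))
    return event_times, n_risk, d


def logrank(groups, times, status) -> LogrankResult:
    """Mantel-Cox log-rank test across two or more groups.

    Uses the hypergeometric variance (and covariance, for more than two
    groups) at every event time; the statistic is compared against a
    chi-square distribution on ``(#groups - 1)`` degrees of freedom.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("logrank requires at least two groups")
    codes = np.searchsorted(labels, g)
    t, s = _as_surv_arrays(times, status)
    k = labels.size
    for li, lab in enumerate(labels):
        if not np.any(codes == li):
            raise ValueError(f"group {lab!r} is empty")
    if not s.any():
        return LogrankResult(0.0, k - 1, 1.0, tuple(labels),
                             np.zeros(k), np.zeros(k))
    _, n_risk, d = _logrank_tables(codes, t, s, k)
    n_tot = n_risk.sum(axis=0)
    d_tot = d.sum(axis=0)
    observed = d.sum(axis=1)
    expected = (d_tot * n_risk / n_tot).sum(axis=1)
    # covariance of (O_g - E_g): hypergeometric at each event time
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(n_tot > 1,
                         d_tot * (n_tot - d_tot) / (n_tot - 1.0), 0.0)
    p_g = n_risk / n_tot  # (k, m)
    cov = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            delta = 1.0 if a == b else 0.0
            cov_ab = float(np.sum(scale * p_g[a] * (delta - p_g[b])))
            cov[a, b] = cov[b, a] = cov_ab
    z = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    p = float(_scipy_stats.chi2.sf(stat, df=k - 1))
    return LogrankResult(stat, k - 1, p, tuple(labels), observed, expected)


def hazard_ratio_oe(times_a, status_a, times_b, status_b,
                    group_a: str = "A", group_b: str = "B") -> HazardRatioResult:
    """O/E hazard ratio of group A relative to group B.

    Both groups must be non-empty and the pooled data must contain at
    least one event.  Swapping the groups inverts the ratio exactly.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    status = np.concatenate([np.asarray(status_a, dtype=bool),
                             np.asarray(status_b, dtype=bool)])
    if not status.any():
        raise ValueError("no events in either group")
    codes = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    _, n_risk, d = _logrank_tables(codes, times, status, 2)
    n_tot = n_risk.sum(axis=0)
    d_tot = d.sum(axis=0)
    o = d.sum(axis=1)
    e = (d_tot * n_risk / n_tot).sum(axis=1)
    o_a, o_b = float(o[0]), float(o[1])
    e_a, e_b = float(e[0]), float(e[1])
    if e_a <= 0 or e_b <= 0 or o_a <= 0 or o_b <= 0:
        return HazardRatioResult(float("nan"), float("nan"), group_a, group_b,
                                 o_a, e_a, o_b, e_b, defined=False)
    hr = (o_a / e_a) / (o_b / e_b)
    se = float(np.sqrt(1.0 / e_a + 1.0 / e_b))
    return HazardRatioResult(hr, se, group_a, group_b,
                             o_a, e_a, o_b, e_b, defined=True)


# ---------------------------------------------------------------------------
# Quartile binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuartileAssignment:
    """Per-patient expression quartile labels for one gene.

    Q1 holds the highest-expression quarter and Q4 the lowest.  Values
    exactly equal to a cutpoint are assigned to the lower-expression bin.
    """

    gene: str
    bins: np.ndarray        # array of "Q1".."Q4" strings
    cutpoints: np.ndarray   # 25th, 50th, 75th empirical percentiles

    def members(self, label: str) -> np.ndarray:
        """Indices of patients assigned to ``label``."""
        return np.flatnonzero(self.bins == label)


def quartile_bins(values, gene: str = "") -> QuartileAssignment:
    """Bin patients into expression quartiles (Q1 high ... Q4 low).

    Cutpoints are the 25/50/75 empirical percentiles under the
    linear-interpolation definition.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 8:
        raise ValueError("quartile binning needs at least 8 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.ptp(v) == 0:
        raise ZeroVarianceError(
            f"gene {gene or '<unnamed>'}: all values identical, "
            "quartiles undefined")
    c25, c50, c75 = np.percentile(v, [25, 50, 75])
    bins = np.empty(v.size, dtype=object)
    bins[v <= c25] = "Q4"
    bins[(v > c25) & (v <= c50)] = "Q3"
    bins[(v > c50) & (v <= c75)] = "Q2"
    bins[v > c75] = "Q1"
    return QuartileAssignment(gene, bins, np.array([c25, c50, c75]))


def median_split(values) -> np.ndarray:
    """Boolean mask of the high-expression half (value > median).

    Ties at the median go to the low group, deterministically.
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ZeroVarianceError("all values identical, median split undefined")
    return v > np.median(v)


# ---------------------------------------------------------------------------
# Rank and correlation statistics
# ---------------------------------------------------------------------------

_EXACT_MW_MAX_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_x, p)``.

    The exact null distribution is enumerated when both samples have at
    most eight observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _scipy_stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    if n <= _EXACT_MW_MAX_N and m <= _EXACT_MW_MAX_N and not has_ties:
        p = _exact_mw_p(u_x, n, m)
        return u_x, p
    mu = n * m / 2.0
    n_tot = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = (n * m / 12.0) * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if var <= 0:
        return u_x, 1.0
    z = max(abs(u_x - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(_scipy_stats.norm.sf(z)))
    return u_x, p


def _exact_mw_p(u_obs: float, n: int, m: int) -> float:
    """Exact two-sided p by enumerating all rank arrangements."""
    total = comb(n + m, n)
    u_min = min(u_obs, n * m - u_obs)
    offset = n * (n + 1) / 2.0
    count = 0
    for subset in combinations(range(1, n + m + 1), n):
        if sum(subset) - offset <= u_min:
            count += 1
    return min(1.0, 2.0 * count / total)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs paired samples of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc ** 2)))
    sy = float(np.sqrt(np.sum(yc ** 2)))
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("zero variance; correlation undefined")
    r = float(np.sum(xc * yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


# ---------------------------------------------------------------------------
# Multiple testing and enrichment
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Output order matches input order; values are monotone-enforced and
    clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_enrichment(k: int, n_query: int, K: int, N: int) -> tuple[float, float]:
    """Upper-tail hypergeometric enrichment probability and fold enrichment.

    ``p = P(X >= k)`` where X counts annotated genes in a random query of
    size ``n_query`` drawn without replacement from a universe of ``N``
    genes of which ``K`` are annotated.  Fold enrichment is
    ``(k/n_query) / (K/N)``.
    """
    if not (0 <= k <= min(n_query, K)):
        raise ValueError("k must satisfy 0 <= k <= min(n_query, K)")
    if not (0 < n_query <= N and 0 < K <= N):
        raise ValueError("require 0 < n_query, K <= N")
    p = float(_scipy_stats.hypergeom.sf(k - 1, N, K, n_query))
    fold = (k / n_query) / (K / N)
    return min(1.0, p), fold
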