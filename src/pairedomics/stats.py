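"""Exact nonparametric tests, BH adjustment, and survival estimators.

The Wilcoxon tests compute exact two-sided p-values by dynamic programming
over the (signed-)rank distribution at small sample sizes and fall back to
a continuity-corrected normal approximation above the exact cutoffs.
Two-sided p-values are twice the smaller tail, capped at 1 — the classical
convention for these discrete distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Largest n for which the signed-rank null is enumerated exactly.
EXACT_SIGNED_RANK_N = 25
#: Largest m + n for which the rank-sum null is enumerated exactly.
EXACT_RANK_SUM_N = 25

_Z975 = sps.norm.ppf(0.975)


@dataclass(frozen=True, slots=True)
class TestResult:
    statistic: float
    p_value: float
    n_used: int
    method: str
    exact: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood log-scale CIs."""

    times: np.ndarray          # distinct event times, increasing
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Counts of subset sums of the doubled ranks (handles mid-ranks exactly).

    Returns (counts, total) where counts[s] is the number of sign
    assignments with doubled positive-rank sum s and total = 2**n.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts, 2 ** len(doubled_ranks)


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Pass paired samples ``x, y`` (differences are ``x - y``) or a single
    array of differences.  Zero differences are dropped before ranking;
    ties receive mid-ranks.  The statistic W is the sum of positive signed
    ranks.  Exact for n <= 25 via enumeration of the signed-rank null
    (valid with mid-ranks), normal approximation with continuity and tie
    correction above.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size != n
    flags: tuple[str, ...] = ("ties",) if has_ties else ()

    if n <= EXACT_SIGNED_RANK_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts, total = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w, p, n, "wilcoxon_signed_rank", True, flags)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(w, p, n, "wilcoxon_signed_rank", False, flags + ("normal_approx",))


def _rank_sum_distribution(m: int, n: int) -> np.ndarray:
    """Counts of rank-sum values for the smaller group of size m out of m+n.

    counts[s] = number of m-subsets of {1..m+n} with sum s (index offset 0).
    """
    total_n = m + n
    max_sum = m * total_n  # loose upper bound
    dp = np.zeros((m + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, total_n + 1):
        for k in range(min(r, m), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[m]


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact for m + n <= 25 without ties, mid-rank normal approximation
    with continuity and tie correction otherwise.  The statistic reported
    is the rank sum W of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValidationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:m].sum())
    has_ties = np.unique(combined).size != m + n
    flags: tuple[str, ...] = ("ties",) if has_ties else ()

    if not has_ties and m + n <= EXACT_RANK_SUM_N:
        counts = _rank_sum_distribution(m, n)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w, p, m + n, "wilcoxon_rank_sum", True, flags)

    mean = m * (m + n + 1) / 2.0
    nt = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((nt) * (nt - 1))
    var = m * n / 12.0 * ((nt + 1) - tie_term)
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(w, p, m + n, "wilcoxon_rank_sum", False, flags + ("normal_approx",))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of nonnegative integers.

    Two-sided p sums all tables (at fixed margins) whose hypergeometric
    probability does not exceed the observed table's.  Returns the sample
    odds ratio (a*d)/(b*c) and the p-value.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(tab < 0) or np.any(tab != np.rint(tab)):
        raise ValidationError("table entries must be nonnegative integers")
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0:
        return np.nan, 1.0
    dist = sps.hypergeom(n_total, row1, col1)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    if alternative == "greater":
        return odds, float(min(1.0, dist.sf(a - 1)))
    if alternative == "less":
        return odds, float(min(1.0, dist.cdf(a)))
    if alternative != "two-sided":
        raise ValidationError(f"unknown alternative {alternative!r}")
    support = np.arange(max(0, col1 - (c + d)), min(col1, row1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return odds, min(1.0, p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def kaplan_meier(times, events, conf_level: float = 0.95) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``events`` is 1/True for an observed event, 0/False for censoring.
    Greenwood variance; confidence interval on the log-survival scale:
    S * exp(+/- z * se(log S)).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(t < 0):
        raise ValidationError("times must be nonnegative")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n_total = t.size
    at_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    surv = np.empty(event_times.size)
    var_log = np.empty(event_times.size)
    s = 1.0
    vlog = 0.0
    for i, et in enumerate(event_times):
        n_at = int((t >= et).sum())
        d = int((e & (t == et)).sum())
        at_risk[i] = n_at
        n_events[i] = d
        s *= (n_at - d) / n_at
        surv[i] = s
        if n_at > d:
            vlog += d / (n_at * (n_at - d))
        else:
            vlog = np.inf
        var_log[i] = vlog
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    se_log = np.sqrt(var_log)
    with np.errstate(invalid="ignore", over="ignore"):
        lower = surv * np.exp(-z * se_log)
        upper = np.minimum(1.0, surv * np.exp(z * se_log))
        variance = surv**2 * var_log  # Greenwood
    return SurvivalCurve(event_times, at_risk, n_events, surv, variance, lower, upper)


def log_rank(times, events, groups) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df).

    If no events are observed the statistic is undefined; a flagged
    result with p = nan is returned rather than an exception.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"log_rank requires exactly 2 groups, got {labels.size}")
    if not e.any():
        return TestResult(np.nan, np.nan, t.size, "log_rank", False, ("no_events",))
    in0 = g == labels[0]
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for et in np.unique(t[e]):
        at_risk = t >= et
        n_at = int(at_risk.sum())
        n0 = int((at_risk & in0).sum())
        d = int((e & (t == et)).sum())
        d0 = int((e & (t == et) & in0).sum())
        observed += d0
        expected += d * n0 / n_at
        if n_at > 1:
            variance += d * (n0 / n_at) * (1 - n0 / n_at) * (n_at - d) / (n_at - 1)
    if variance == 0:
        return TestResult(np.nan, np.nan, t.size, "log_rank", False, ("zero_variance",))
    chi2 = (observed - expected) ** 2 / variance
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, t.size, "log_rank", False)
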