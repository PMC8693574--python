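"""Nonparametric tests used by the cohort analyses.

Thin, contract-preserving wrappers around scipy.stats:

* Kendall's tau-b with tie correction (exact enumeration p-value for
  n ≤ 8 without ties, tie-adjusted normal approximation otherwise);
* Mann–Whitney U with midrank ties (exact p for n1+n2 ≤ 20 without
  ties, tie-corrected normal approximation otherwise);
* one-sample Wilcoxon signed-rank vs a reference value (exact p for
  n ≤ 15 after dropping zeros, else normal approximation with
  continuity correction), reporting the standardized Z alongside.

Each returns a :class:`StatResult` carrying the statistic, sample
size(s), p-value, sidedness and whether a tie correction applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    sidedness: str = "two-sided"
    tie_correction: bool = False
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _has_ties(*arrays) -> bool:
    return any(len(np.unique(a)) < len(a) for a in arrays)


def kendall_tau_b(x, y, sided: str = "two-sided") -> StatResult:
    """Kendall's tau-b rank correlation between paired samples.

    Pairs with a missing value in either coordinate are dropped first.
    With fewer than 3 complete pairs, or a constant margin (tau
    undefined), the result is flagged not estimable rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return StatResult(method="kendall_tau_b", statistic=float("nan"),
                          p_value=float("nan"), n=n, sidedness=sided,
                          estimable=False)
    ties = _has_ties(x, y)
    method = "exact" if (n <= 8 and not ties) else "asymptotic"
    res = sps.kendalltau(x, y, method=method, alternative=sided)
    return StatResult(method="kendall_tau_b", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=n, sidedness=sided,
                      tie_correction=ties)


def mann_whitney_u(a, b, sided: str = "two-sided") -> StatResult:
    """Mann–Whitney U test between two independent samples.

    Reports ``U_min = min(U1, U2)`` as the statistic.  Exact p-value
    for small tie-free samples, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ties = _has_ties(np.concatenate([a, b]))
    method = "exact" if (n1 + n2 <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=sided, method=method)
    u1 = float(res.statistic)
    u_min = min(u1, n1 * n2 - u1)
    return StatResult(method="mann_whitney_u", statistic=u_min,
                      p_value=float(res.pvalue), n1=n1, n2=n2,
                      sidedness=sided, tie_correction=ties)


def wilcoxon_one_sample(x, mu: float = 0.0, sided: str = "two-sided") -> StatResult:
    """One-sample Wilcoxon signed-rank test of location against ``mu``.

    Differences exactly equal to ``mu`` are dropped (Wilcoxon's
    convention).  The statistic reported is the standardized Z of the
    signed-rank sum; the p-value is exact for n ≤ 15 (no tied absolute
    differences), else from the normal approximation with continuity
    correction.  ``sided`` ∈ {"two-sided", "greater", "less"} tests the
    location of ``x`` relative to ``mu``.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    d = x - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal the reference; test undefined")
    ties = _has_ties(np.abs(d))
    method = "exact" if (n <= 15 and not ties) else "approx"
    res = sps.wilcoxon(d, alternative=sided, method=method, correction=True)
    # standardized Z from the signed-rank sum (tie-corrected variance)
    ranks = sps.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts) / 48.0
    z = (w - mean_w) / np.sqrt(var_w) if var_w > 0 else float("nan")
    return StatResult(method="wilcoxon_one_sample", statistic=float(z),
                      p_value=float(res.pvalue), n=n, sidedness=sided,
                      tie_correction=ties)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default).

    NaNs (not-estimable cells) are passed through unadjusted and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
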