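"""Nonparametric trend estimation for annual spring-timing series.

The Kendall-Theil (Theil-Sen) slope — the median of all pairwise slopes — is
paired with the Mann-Kendall S test for monotone trend (tie-corrected normal
approximation with continuity correction), and a lag-1 autocorrelation
pre-check. Trends are reported both per year and per decade; series flagged by
the autocorrelation check are annotated, not suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, theilslopes

from .exceptions import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "TrendResult",
    "theil_sen",
    "mann_kendall",
    "lag1_autocorrelation",
    "trend_test",
]


@dataclass(frozen=True)
class TrendResult:
    slope_per_year: float
    slope_per_decade: float
    intercept: float
    mk_S: int
    mk_p: float
    significant: bool
    lag1_autocorr: float
    autocorr_flagged: bool
    n: int


def theil_sen(x, y) -> tuple[float, float]:
    """Kendall-Theil line fit.

    Slope is the median of all pairwise slopes ``(y_j - y_i)/(x_j - x_i)``,
    i < j; intercept is ``median(y - slope * x)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    res = theilslopes(y, x, method="joint")
    return float(res.slope), float(res.intercept)


def theil_sen_brute(x, y) -> tuple[float, float]:
    """Direct enumeration of all pairwise slopes (independent cross-check)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slopes = [(y[j] - y[i]) / (x[j] - x[i]) for i, j in combinations(range(x.size), 2)]
    slope = float(np.median(slopes))
    return slope, float(np.median(y - slope * x))


def mann_kendall(y) -> tuple[int, float]:
    """Mann-Kendall trend test.

    ``S = sum_{i<j} sign(y_j - y_i)``; variance with tie correction
    ``Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` over tie groups of
    size ``t``; two-sided p from the normal approximation with continuity
    correction ``Z = (S -/+ 1)/sqrt(Var(S))``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 points, got {n}")
    diff = np.sign(y[None, :] - y[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        # every value tied: no evidence of trend
        return s, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(2.0 * norm.sf(abs(z)))
    return s, min(p, 1.0)


def lag1_autocorrelation(y) -> tuple[float, bool]:
    """Lag-1 sample autocorrelation and a ``|r1| > 1.96/sqrt(n)`` flag."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise InsufficientDataError(f"need >= 5 points, got {n}")
    dev = y - y.mean()
    denom = float(np.sum(dev * dev))
    if denom == 0:
        raise UndefinedStatisticError("constant series: autocorrelation undefined")
    r1 = float(np.sum(dev[:-1] * dev[1:]) / denom)
    return r1, abs(r1) > 1.96 / np.sqrt(n)


def trend_test(x, y, alpha: float = 0.05) -> TrendResult:
    """Full trend workup: Theil-Sen fit, Mann-Kendall p, autocorrelation flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = theil_sen(x, y)
    s, p = mann_kendall(y)
    try:
        r1, flagged = lag1_autocorrelation(y)
    except UndefinedStatisticError:
        r1, flagged = 0.0, False
    return TrendResult(
        slope_per_year=slope,
        slope_per_decade=10.0 * slope,
        intercept=intercept,
        mk_S=s,
        mk_p=p,
        significant=p < alpha,
        lag1_autocorr=r1,
        autocorr_flagged=flagged,
        n=int(y.size),
    )
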