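"""Small statistical primitives shared across modules.

The log-space binomial tail is authored here because the transitivity
evaluation needs probabilities far below the smallest positive float; the
rank-based helpers wrap scipy.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp


def binomial_upper_tail(k: int, n: int, p: float) -> tuple[float, float]:
    """Exact upper-tail binomial probability P(X >= k | n, p), log-safe.

    Returns ``(probability, log10_probability)``. The sum is carried out in
    log space so magnitudes far below the double-precision underflow
    threshold (~1e-308) still yield a finite log10; the returned linear
    probability underflows to 0.0 in that regime.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if k == 0:
        return 1.0, 0.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    log_p = float(logsumexp(log_terms))
    log10_p = min(log_p / math.log(10.0), 0.0)
    return float(math.exp(log_p)) if log_p > -700 else 0.0, log10_p


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for z.

    Computed as the Pearson correlation of the residuals of rank(x) and
    rank(y) after linear regression on rank(z).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)
    if len(rx) < 4:
        raise ValueError("partial correlation needs at least 4 observations")

    def residuals(r: np.ndarray) -> np.ndarray:
        slope, intercept = np.polyfit(rz, r, 1)
        return r - (slope * rz + intercept)

    ex, ey = residuals(rx), residuals(ry)
    if np.allclose(ex, 0.0) or np.allclose(ey, 0.0):
        return 0.0, 1.0
    rho, p = stats.pearsonr(ex, ey)
    return float(rho), float(p)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small untied samples (combined
    n <= 20) and the tie-corrected normal approximation otherwise. Returns
    ``(U statistic for sample a, p value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
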