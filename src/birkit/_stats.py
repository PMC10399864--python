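"""Small shared statistical primitives.

These are the two pieces of interval/test arithmetic that several assay
modules need with identical conventions: the exact (Clopper-Pearson)
binomial confidence interval, and a two-sided exact binomial test whose
p-value is the doubled smaller tail, capped at 1.
"""

from __future__ import annotations

from scipy import stats

from .errors import InputError


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial CI for a proportion ``k/n``.

    Returns ``(lo, hi)`` with guaranteed >= 1 - alpha coverage. The bounds
    are beta-distribution quantiles; the interval collapses appropriately at
    k = 0 (lo = 0) and k = n (hi = 1).
    """
    if not 0 <= k <= n or n < 1:
        raise InputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def binom_test_doubled(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value: twice the smaller tail, capped at 1.

    This convention (rather than the minimum-likelihood two-sided region)
    is symmetric in the marker labels at p0 = 0.5, where the two definitions
    coincide.
    """
    if not 0 <= k <= n or n < 1:
        raise InputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise InputError(f"null proportion must be in [0, 1], got {p0}")
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))
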