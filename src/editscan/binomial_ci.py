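"""Binomial likelihood-ratio (Wilks) confidence intervals for editing
frequencies.

The interval for a frequency given k edited reads out of n is the set of p
whose deviance ``2 * (loglik(k/n) - loglik(p))`` does not exceed the
chi-square(1) quantile at the requested level. Bounds are found by bisection
on each side of the maximum-likelihood estimate; the deviance is unimodal in
p so bisection brackets are guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import xlogy

from editscan.errors import ValidationError

_TOL = 1e-8


@dataclass(frozen=True)
class EditingCI:
    """Editing-frequency point estimate with likelihood-ratio CI bounds."""

    f_hat: float
    lower: float
    upper: float
    level: float
    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.f_hat <= self.upper <= 1.0):
            raise ValidationError(
                f"CI bounds out of order: {self.lower}, {self.f_hat}, {self.upper}"
            )
        if self.n < 1:
            raise ValidationError("n must be >= 1")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def binomial_loglik(k: int, n: int, p: float) -> float:
    """Binomial log-likelihood ``k*log(p) + (n-k)*log(1-p)``.

    Uses the convention 0*log(0) = 0; returns -inf when p = 0 with k > 0 or
    p = 1 with k < n. The binomial coefficient is omitted — it cancels in
    every likelihood ratio.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    return float(xlogy(k, p) + xlogy(n - k, 1.0 - p))


def _deviance(k: int, n: int, p: float, ll_max: float) -> float:
    return 2.0 * (ll_max - binomial_loglik(k, n, p))


def _bisect(k, n, ll_max, q, lo, hi, increasing_deviance):
    """Bisection for the p with deviance == q on a monotone flank.

    ``increasing_deviance`` is True on the upper flank (deviance grows as p
    moves up away from f_hat) and False on the lower flank.
    """
    while hi - lo > _TOL:
        mid = 0.5 * (lo + hi)
        if (_deviance(k, n, mid, ll_max) > q) == increasing_deviance:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=200_000)
def wilks_ci(k: int, n: int, level: float = 0.95) -> EditingCI:
    """Likelihood-ratio confidence interval for a binomial proportion.

    The lower bound is exactly 0 when k = 0 and the upper bound exactly 1
    when k = n. Bounds are accurate to 1e-8 in p.
    """
    k = int(k)
    n = int(n)
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    f_hat = k / n
    q = float(stats.chi2.ppf(level, df=1))
    ll_max = binomial_loglik(k, n, f_hat)
    if k == 0:
        lower = 0.0
    else:
        # deviance decreases from +inf at p=0 down to 0 at f_hat
        lower = _bisect(k, n, ll_max, q, 0.0, f_hat, increasing_deviance=False)
    if k == n:
        upper = 1.0
    else:
        upper = _bisect(k, n, ll_max, q, f_hat, 1.0, increasing_deviance=True)
    # bisection can land a hair on the wrong side of f_hat for extreme k/n
    lower = min(lower, f_hat)
    upper = max(upper, f_hat)
    return EditingCI(f_hat=f_hat, lower=lower, upper=upper, level=level, k=k, n=n)


def ci_to_sd(ci: EditingCI) -> float:
    """Map a CI to a standard-deviation scale for inverse-variance weighting.

    sigma = (upper - lower) / (2 z), with z the two-sided normal quantile at
    the CI's level, floored at 1/(2n) so boundary sites (k=0 or k=n) never
    get infinite weight.
    """
    z = float(stats.norm.ppf(0.5 * (1.0 + ci.level)))
    sigma = ci.width / (2.0 * z)
    return max(sigma, 1.0 / (2.0 * ci.n))
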