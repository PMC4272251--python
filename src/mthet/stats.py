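"""Exact statistical machinery.

Three tools used throughout the pipeline:

* Clopper-Pearson exact binomial confidence intervals for heteroplasmy
  fractions v/n (guaranteed coverage >= the nominal level);
* the exact Poisson rate-ratio test for comparing per-base discordance rates
  between sequencing platforms, performed conditionally on the total count as
  an exact binomial test with the two-sided minimum-likelihood p-value;
* Pearson product-moment correlation, reported as R^2 with the t-transform
  p-value, for coverage vs copy-number comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import DataError

#: relative slack when comparing point probabilities in the minimum-likelihood
#: two-sided p-value (guards against floating-point ties, cf. R's binom.test)
_REL_TOL = 1 + 1e-7


@dataclass(frozen=True)
class ExactInterval:
    """An exact (Clopper-Pearson) binomial confidence interval for v/n."""

    v: int
    n: int
    level: float
    low: float
    high: float

    @property
    def point(self) -> float:
        return self.v / self.n

    def contains(self, p: float) -> bool:
        return self.low <= p <= self.high


def clopper_pearson(v: int, n: int, level: float = 0.95) -> ExactInterval:
    """Exact binomial confidence interval via the beta-quantile identity.

    ``low`` solves P(X >= v | n, p) = (1-level)/2 (0 when v = 0) and ``high``
    solves P(X <= v | n, p) = (1-level)/2 (1 when v = n); the solutions are
    Beta(v, n-v+1) and Beta(v+1, n-v) quantiles.
    """
    if n < 1:
        raise DataError("clopper_pearson: n must be >= 1")
    if not 0 <= v <= n:
        raise DataError(f"clopper_pearson: v={v} outside [0, n={n}]")
    if not 0 < level < 1:
        raise DataError("clopper_pearson: level must be in (0, 1)")
    alpha = 1 - level
    low = 0.0 if v == 0 else float(_sps.beta.ppf(alpha / 2, v, n - v + 1))
    high = 1.0 if v == n else float(_sps.beta.ppf(1 - alpha / 2, v + 1, n - v))
    return ExactInterval(v=v, n=n, level=level, low=low, high=high)


@dataclass(frozen=True)
class RateRatioTest:
    """Exact test of equal event rates in two Poisson processes."""

    count_a: int
    count_b: int
    exposure_a: float
    exposure_b: float
    estimate: float
    p_value: float


def poisson_ratio_test(
    count_a: int, count_b: int, exposure_a: float, exposure_b: float
) -> RateRatioTest:
    """Exact Poisson rate-ratio test of the null ratio 1.

    Conditional on the total T = count_a + count_b, count_a is
    Binomial(T, exposure_a / (exposure_a + exposure_b)) under the null; the
    two-sided p-value sums all binomial point probabilities not exceeding
    that of the observed count (minimum-likelihood method).
    """
    if count_a < 0 or count_b < 0:
        raise DataError("poisson_ratio_test: counts must be non-negative")
    if exposure_a <= 0 or exposure_b <= 0:
        raise DataError("poisson_ratio_test: exposures must be positive")
    total = count_a + count_b
    if total < 1:
        raise DataError("poisson_ratio_test: needs at least one event")
    p0 = exposure_a / (exposure_a + exposure_b)
    k = np.arange(total + 1)
    pmf = _sps.binom.pmf(k, total, p0)
    p_obs = pmf[count_a]
    p_value = float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))
    rate_a = count_a / exposure_a
    rate_b = count_b / exposure_b
    estimate = math.inf if count_b == 0 else rate_a / rate_b
    return RateRatioTest(count_a, count_b, exposure_a, exposure_b, estimate, p_value)


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson correlation; returns (r_squared, two-sided p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson: x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DataError("pearson: need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("pearson: correlation undefined for a constant vector")
    res = _sps.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue), n
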