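"""Trend tests, summary statistics and the two-group sample-size formula.

The regression and sample-size computations are written out from their
closed forms (normal equations, normal-approximation power formula) with
scipy supplying only the t and standard-normal distribution functions;
``scipy.stats.linregress`` serves as an independent cross-check in the test
suite, never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TrendResult",
    "PowerSpec",
    "linear_trend",
    "sample_size_two_means",
    "circular_or_linear_summary",
    "type_one_error_rate",
]


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-group mean-comparison sample-size computation."""

    alpha: float = 0.05
    power: float = 0.8
    mu_a: float = 2.6
    mu_b: float = 5.7
    sd: float = 2.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def linear_trend(x, y) -> TrendResult:
    """Ordinary least-squares trend with a two-sided t-test on the slope.

    slope = Sxy/Sxx, se = sqrt(SSE/(n-2)/Sxx), t = slope/se with n-2
    degrees of freedom; the p-value uses the exact t distribution, which
    matters at per-sequence frame counts (~30).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 0:
        raise ValueError("x is constant; trend undefined")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    df = n - 2
    se2 = sse / df / sxx
    if se2 == 0.0:
        # perfect fit: the t statistic diverges
        return TrendResult(slope=slope, intercept=intercept, t_statistic=math.inf if slope > 0 else (-math.inf if slope < 0 else 0.0), p_value=0.0 if slope != 0 else 1.0, n=n)
    t_stat = slope / math.sqrt(se2)
    p = 2.0 * float(_sps.t.sf(abs(t_stat), df))
    return TrendResult(slope=slope, intercept=intercept, t_statistic=t_stat, p_value=p, n=n)


def sample_size_two_means(spec: PowerSpec) -> int:
    """Per-group n for detecting a difference of two means.

    n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / (mu_a - mu_b)^2 ),
    the standard normal-approximation formula for a two-sided two-sample
    comparison of means with common standard deviation.
    """
    delta = spec.mu_a - spec.mu_b
    if delta == 0:
        raise ValueError("equal means: required sample size is unbounded")
    z_alpha = float(_sps.norm.ppf(1 - spec.alpha / 2))
    z_beta = float(_sps.norm.ppf(spec.power))
    n = 2.0 * (z_alpha + z_beta) ** 2 * spec.sd**2 / delta**2
    return int(math.ceil(n))


def circular_or_linear_summary(values) -> tuple[float, float, float, float]:
    """(mean, sample SD, min, max) of angle data treated linearly.

    All the angles summarized here stay well below 90 deg, so no circular
    wraparound handling is needed.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 values")
    return (
        float(values.mean()),
        float(values.std(ddof=1)),
        float(values.min()),
        float(values.max()),
    )


def type_one_error_rate(
    n_sims: int = 1000,
    n: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of :func:`linear_trend` under the null.

    x is a fixed grid; y is drawn i.i.d. standard normal, independent of x,
    so any rejection is a type-I error.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    rejections = 0
    for _ in range(n_sims):
        y = rng.standard_normal(n)
        if linear_trend(x, y).p_value < alpha:
            rejections += 1
    return rejections / n_sims
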