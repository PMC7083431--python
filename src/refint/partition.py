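"""Harris-Boyd partitioning and rank correlation.

Whether sex or age subgroups need separate reference intervals is decided
by the Harris-Boyd standard-normal-deviate test: the statistic

    z = |m1 - m2| / sqrt(s1^2/n1 + s2^2/n2)

is compared not with a fixed Gaussian quantile but with the sample-size
scaled critical value

    z* = 3 * sqrt(((n1 + n2) / 2) / 120)

so that the trivially significant mean differences produced by very large
routine cohorts only trigger partitioning when they are large relative to
what a 120-per-group reference study would resolve.  z > z* means the
subgroups warrant separate intervals.

Age trends are quantified by Spearman rank correlation (average ranks for
ties; p-value from the t approximation with n-2 degrees of freedom).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transform import DEFAULT_LAMBDA_BOUNDS, boxcox, fit_lambda_mle

__all__ = [
    "GroupSummary",
    "PartitionDecision",
    "CorrelationResult",
    "summarize",
    "harris_boyd_z",
    "harris_boyd_critical",
    "decide_partition",
    "spearman_rho",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    scale: str  # "raw" or "transformed"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class PartitionDecision:
    z: float
    z_star: float
    separate: bool
    scale_used: str
    lam: float | None = None  # pooled Box-Cox lambda when scale_used == "transformed"


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def summarize(values, scale: str = "raw") -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(n=values.size, mean=float(values.mean()),
                        sd=float(values.std(ddof=1)), scale=scale)


def harris_boyd_z(g1: GroupSummary, g2: GroupSummary) -> float:
    """Standard normal deviate between two group means."""
    if g1.scale != g2.scale:
        raise ValueError(f"summaries on different scales: {g1.scale!r} vs {g2.scale!r}")
    return abs(g1.mean - g2.mean) / math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)


def harris_boyd_critical(n1: int, n2: int) -> float:
    """Sample-size scaled critical value z* = 3*sqrt(((n1+n2)/2)/120)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be at least 1")
    return 3.0 * math.sqrt(((n1 + n2) / 2.0) / 120.0)


def decide_partition(
    values1,
    values2,
    scale: str = "transformed",
    crit_ns: tuple[int, int] | None = None,
    lam: float | None = None,
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> PartitionDecision:
    """Decide whether two subgroups warrant separate reference intervals.

    By default the comparison is made on the Box-Cox transformed scale with
    a single lambda fitted to the pooled data of both subgroups (pass
    ``lam`` to reuse a pre-fitted value), so the two means are compared on
    a common near-Gaussian scale; ``scale="raw"`` compares original units.

    ``crit_ns`` supplies the sample sizes used for z* — by convention the
    subgroup sizes before outlier deletion; defaults to the sizes of the
    inputs.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if scale == "transformed":
        if lam is None:
            lam = fit_lambda_mle(np.concatenate([v1, v2]), bounds=lambda_bounds).lam
        g1 = summarize(boxcox(v1, lam), scale="transformed")
        g2 = summarize(boxcox(v2, lam), scale="transformed")
    elif scale == "raw":
        g1, g2 = summarize(v1), summarize(v2)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    n1, n2 = crit_ns if crit_ns is not None else (v1.size, v2.size)
    z = harris_boyd_z(g1, g2)
    z_star = harris_boyd_critical(n1, n2)
    return PartitionDecision(z=z, z_star=z_star, separate=z > z_star,
                             scale_used=scale, lam=lam if scale == "transformed" else None)


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("rank correlation needs at least 3 pairs")
    if x.size < 10:
        warnings.warn("rank correlation on n < 10: p-value unreliable", stacklevel=2)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=x.size)
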