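"""95% reference intervals with 90% confidence intervals for both limits.

Two routes, following CLSI EP28-A3 conventions:

* **parametric** — Box-Cox transform to a near-Gaussian scale, take
  mean +/- 1.96*SD, back-transform.  The 90% CI of each limit uses
  Var(xbar +/- z*s) ~= s^2 * (1/n + z^2 / (2*(n-1))) on the transformed
  scale before back-transformation.
* **non-parametric** — the empirical 2.5th and 97.5th percentiles at ranks
  0.025*(n+1) and 0.975*(n+1) (linear interpolation between order
  statistics), with distribution-free 90% CIs whose endpoints are the order
  statistics bracketing the point rank with >= 90% binomial coverage.

Both routes expect an outlier-deleted sample (see :mod:`refint.outliers`).
``build_ri_table`` assembles the per-subgroup table — distribution tests
before/after transformation and outlier deletion, iteration counts, and
both interval routes — for a cleaned cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .disttests import DistributionTest, skewness_kurtosis
from .outliers import OutlierReport, remove_outliers_iterative
from .transform import (
    DEFAULT_LAMBDA_BOUNDS,
    boxcox,
    fit_lambda_mle,
    inverse_boxcox,
)

__all__ = [
    "ReferenceInterval",
    "GroupResult",
    "rank_quantile",
    "order_statistic_ci_ranks",
    "parametric_ri",
    "nonparametric_ri",
    "build_ri_table",
]

Z_95 = 1.96    # central 95% reference interval
Z_90CI = 1.645  # 90% confidence interval of each limit


@dataclass
class ReferenceInterval:
    """A 95% reference interval on the original (ug/L) scale.

    ``lower``/``upper`` may be NaN when a parametric limit falls outside
    the domain of the inverse Box-Cox transform; the transformed-scale
    values are then kept in ``transformed_limits`` and a note records why.
    """

    lower: float
    upper: float
    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]
    method: str                     # "parametric" | "nonparametric"
    n: int
    lam: float | None = None        # Box-Cox lambda (parametric route only)
    transformed_limits: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)


def rank_quantile(values, p: float) -> float:
    """Percentile by the rank rule p*(n+1), interpolated, clamped to [1, n]."""
    return float(np.quantile(np.asarray(values, dtype=float), p, method="weibull"))


def order_statistic_ci_ranks(n: int, p: float, conf: float = 0.90) -> tuple[int, int]:
    """1-based order-statistic ranks (r, s) bracketing the p-th quantile.

    Chooses the smallest bracket, as symmetric as possible around the point
    rank ``p*(n+1)``, whose distribution-free coverage
    ``P(X_(r) <= q_p <= X_(s)) = BinCDF(s-1; n, p) - BinCDF(r-1; n, p)``
    reaches ``conf``.
    """
    h = min(max(p * (n + 1), 1.0), float(n))
    r = int(math.floor(h))
    s = int(math.ceil(h))
    if s == r:
        s = min(r + 1, n)
        if s == r:  # n == 1 degenerate
            return r, s

    def coverage(r_: int, s_: int) -> float:
        return float(stats.binom.cdf(s_ - 1, n, p) - stats.binom.cdf(r_ - 1, n, p))

    while coverage(r, s) < conf:
        # expand the side that keeps the bracket balanced around h
        if r > 1 and (h - r <= s - h or s >= n):
            r -= 1
        elif s < n:
            s += 1
        else:
            break  # widest possible bracket
    return r, s


def parametric_ri(
    values,
    lam: float | None = None,
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> ReferenceInterval:
    """Parametric 95% RI (mean +/- 1.96 SD on the Box-Cox scale).

    ``lam`` defaults to the maximum-likelihood fit on ``values`` — pass the
    final lambda from the outlier-deletion loop to reuse it.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 120:
        warnings.warn("parametric RI on n < 120: confidence intervals are unreliable",
                      stacklevel=2)
    if lam is None:
        lam = fit_lambda_mle(values, bounds=lambda_bounds).lam
    t = boxcox(values, lam)
    m, s = float(t.mean()), float(t.std(ddof=1))
    t_lower, t_upper = m - Z_95 * s, m + Z_95 * s
    se_limit = s * math.sqrt(1.0 / n + Z_95**2 / (2.0 * (n - 1)))

    notes: list[str] = []

    def back(y: float, label: str) -> float:
        try:
            return float(inverse_boxcox(y, lam))
        except ValueError:
            notes.append(
                f"{label} not representable on the original scale "
                f"(transformed value {y:.6g}, lambda {lam:.4g})"
            )
            return float("nan")

    lower = back(t_lower, "lower limit")
    upper = back(t_upper, "upper limit")
    lower_ci = (back(t_lower - Z_90CI * se_limit, "lower-limit CI low"),
                back(t_lower + Z_90CI * se_limit, "lower-limit CI high"))
    upper_ci = (back(t_upper - Z_90CI * se_limit, "upper-limit CI low"),
                back(t_upper + Z_90CI * se_limit, "upper-limit CI high"))
    return ReferenceInterval(
        lower=lower, upper=upper, lower_ci=lower_ci, upper_ci=upper_ci,
        method="parametric", n=n, lam=float(lam),
        transformed_limits=(t_lower, t_upper), notes=notes,
    )


def nonparametric_ri(values, round_values: bool = False) -> ReferenceInterval:
    """Non-parametric 95% RI (2.5th / 97.5th percentiles, order-statistic CIs).

    ``round_values`` rounds the inputs to integers first, emulating assays
    that report whole units; on such discretised data the CI of a limit can
    legitimately collapse to a single repeated value.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 40:
        raise ValueError("sample too small for nonparametric RI (need n >= 40)")
    if n < 120:
        warnings.warn("nonparametric RI on n < 120: percentile limits are imprecise",
                      stacklevel=2)
    if round_values:
        values = np.round(values)
    ordered = np.sort(values)
    lower = rank_quantile(ordered, 0.025)
    upper = rank_quantile(ordered, 0.975)
    r_lo, s_lo = order_statistic_ci_ranks(n, 0.025)
    r_hi, s_hi = order_statistic_ci_ranks(n, 0.975)
    return ReferenceInterval(
        lower=lower, upper=upper,
        lower_ci=(float(ordered[r_lo - 1]), float(ordered[s_lo - 1])),
        upper_ci=(float(ordered[r_hi - 1]), float(ordered[s_hi - 1])),
        method="nonparametric", n=n,
    )


@dataclass
class GroupResult:
    """Everything reported for one subgroup of the cohort."""

    name: str
    n: int                          # before outlier deletion
    outliers: OutlierReport
    dist_before: DistributionTest          # raw scale, outliers undeleted
    dist_before_transformed: DistributionTest
    dist_after: DistributionTest           # raw scale, outliers deleted
    dist_after_transformed: DistributionTest
    parametric: ReferenceInterval
    nonparametric: ReferenceInterval


def _analyze_group(
    name: str,
    values: np.ndarray,
    alpha: float,
    max_iter: int,
    lambda_bounds: tuple[float, float],
    round_nonparametric: bool,
) -> GroupResult:
    pre_lam = fit_lambda_mle(values, bounds=lambda_bounds).lam
    rep = remove_outliers_iterative(values, max_iter=max_iter, lambda_bounds=lambda_bounds)
    final = rep.final_values
    return GroupResult(
        name=name,
        n=values.size,
        outliers=rep,
        dist_before=skewness_kurtosis(values, alpha),
        dist_before_transformed=skewness_kurtosis(boxcox(values, pre_lam), alpha),
        dist_after=skewness_kurtosis(final, alpha),
        dist_after_transformed=skewness_kurtosis(boxcox(final, rep.final_lambda), alpha),
        parametric=parametric_ri(final, lam=rep.final_lambda, lambda_bounds=lambda_bounds),
        nonparametric=nonparametric_ri(final, round_values=round_nonparametric),
    )


def build_ri_table(
    data: pd.DataFrame,
    sex_split: bool = True,
    female_age_split: bool = True,
    age_break: int = 50,
    alpha: float = 0.05,
    max_iter: int = 20,
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    round_nonparametric: bool = False,
) -> list[GroupResult]:
    """Per-subgroup RI table for a cleaned cohort.

    ``data`` needs columns ``sex``, ``age``, ``value``.  Groups follow the
    partition verdicts: sexes separately when ``sex_split`` (a pooled group
    otherwise), and females additionally split at ``age_break`` when
    ``female_age_split`` — the aggregate female group is still reported
    alongside its age subgroups.  Sexes absent from the data are simply not
    reported.
    """
    groups: list[tuple[str, pd.Series]] = []
    if sex_split:
        males = data.loc[data["sex"] == "male", "value"]
        females = data.loc[data["sex"] == "female"]
        if len(males):
            groups.append(("males", males))
        if len(females):
            groups.append(("all_females", females["value"]))
            if female_age_split:
                groups.append(
                    (f"females_lt_{age_break}",
                     females.loc[females["age"] < age_break, "value"]))
                groups.append(
                    (f"females_ge_{age_break}",
                     females.loc[females["age"] >= age_break, "value"]))
    else:
        groups.append(("all", data["value"]))

    results = []
    for name, series in groups:
        values = series.to_numpy(dtype=float)
        if values.size == 0:
            continue
        results.append(
            _analyze_group(name, values, alpha, max_iter, lambda_bounds,
                           round_nonparametric)
        )
    return results
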