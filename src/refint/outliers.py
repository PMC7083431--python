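"""Iterative Tukey-fence outlier elimination on the Box-Cox scale.

Routine laboratory data mix a healthy majority with a diseased minority;
the diseased tail is what outlier deletion is meant to strip before a
reference interval is computed.  Each iteration:

1. fit the Box-Cox lambda to the CURRENT sample (maximum likelihood),
2. transform,
3. compute Tukey fences  P25 - 1.5*IQR  and  P75 + 1.5*IQR,
4. delete every value strictly outside the fences as one batch,

and the loop repeats on the survivors until an iteration deletes nothing.
Quartiles use the rank rule p*(n+1) with linear interpolation between order
statistics (numpy's "weibull" method), the same convention the interval
module uses for percentile limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transform import DEFAULT_LAMBDA_BOUNDS, boxcox, fit_lambda_mle

__all__ = ["IterationRecord", "OutlierReport", "tukey_fences", "remove_outliers_iterative"]


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    p25, p75 = np.quantile(values, [0.25, 0.75], method="weibull")
    return float(p25), float(p75)


def tukey_fences(values) -> tuple[float, float]:
    """Lower and upper Tukey fences of ``values`` (any scale).

    Returns ``(P25 - 1.5*IQR, P75 + 1.5*IQR)``.  Needs n >= 4 so that both
    quartiles are interior rank positions.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("Tukey fences need at least 4 values")
    p25, p75 = _quartiles(values)
    iqr = p75 - p25
    return p25 - 1.5 * iqr, p75 + 1.5 * iqr


@dataclass
class IterationRecord:
    """Bookkeeping for one deletion pass (fences on the transformed scale)."""

    lam: float
    p25: float
    p75: float
    iqr: float
    lower_fence: float
    upper_fence: float
    n_removed: int


@dataclass
class OutlierReport:
    iterations: list[IterationRecord]
    total_removed: int
    final_values: np.ndarray = field(repr=False)  # original scale
    final_lambda: float
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def remove_outliers_iterative(
    values,
    max_iter: int = 20,
    refit_lambda: bool = True,
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    min_n: int = 20,
) -> OutlierReport:
    """Delete Tukey outliers on the transformed scale until none remain.

    Parameters
    ----------
    values
        Strictly positive observations on the original scale, n >= ``min_n``.
    max_iter
        Safety cap on deletion passes; reaching it with outliers still
        present records ``converged=False`` and emits a warning.
    refit_lambda
        Re-estimate lambda on the surviving sample every pass (default).
        ``False`` freezes the lambda fitted on the initial sample.

    Notes
    -----
    Deletion is batch-per-iteration: the fences are computed once per pass
    and every value strictly outside them is removed together, so removing
    one flagged value can never un-flag another within the same pass.  The
    final recorded iteration always has ``n_removed == 0`` unless the
    iteration cap was hit.
    """
    current = np.asarray(values, dtype=float)
    if current.size < min_n:
        raise ValueError(f"iterative outlier removal needs at least {min_n} values")

    iterations: list[IterationRecord] = []
    lam: float | None = None
    converged = False
    for _ in range(max_iter):
        if refit_lambda or lam is None:
            lam = fit_lambda_mle(current, bounds=lambda_bounds).lam
        t = boxcox(current, lam)
        p25, p75 = _quartiles(t)
        iqr = p75 - p25
        lo, hi = p25 - 1.5 * iqr, p75 + 1.5 * iqr
        outside = (t < lo) | (t > hi)
        n_removed = int(outside.sum())
        iterations.append(
            IterationRecord(lam=lam, p25=p25, p75=p75, iqr=iqr,
                            lower_fence=lo, upper_fence=hi, n_removed=n_removed)
        )
        if n_removed == 0:
            converged = True
            break
        current = current[~outside]
        if current.size < min_n:
            raise ValueError("sample shrank below the minimum size during outlier removal")
    if not converged:
        warnings.warn(
            f"outlier removal hit the iteration cap ({max_iter}) with outliers still present",
            stacklevel=2,
        )
    return OutlierReport(
        iterations=iterations,
        total_removed=int(sum(r.n_removed for r in iterations)),
        final_values=current,
        final_lambda=float(lam),
        converged=converged,
    )
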