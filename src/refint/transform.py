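"""Box-Cox power transformation with maximum-likelihood lambda.

The transform maps a positive, right-skewed analyte distribution onto an
approximately Gaussian scale:

    x(lam) = (x**lam - 1) / lam   for lam != 0
    x(lam) = ln(x)                for lam == 0

lambda is chosen by maximising the normal-theory profile log-likelihood

    llf(lam) = -(n/2) * ln(sigma_hat^2(lam)) + (lam - 1) * sum(ln x)

where sigma_hat^2 is the MLE variance of the transformed values; the second
term is the Jacobian of the transformation.  The inverse transform is used
to express reference limits computed on the transformed scale back in
original units (ug/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["TransformResult", "boxcox", "inverse_boxcox", "boxcox_loglik", "fit_lambda_mle"]

#: lambdas closer to zero than this use the ln branch (numerically identical
#: to well below float precision of the power branch).
_LAM_EPS = 1e-12

#: default maximum-likelihood search interval for lambda; covers every
#: physiologically plausible skew regime (lam=1 no skew, lam=0 lognormal,
#: lam<0 heavier than lognormal).
DEFAULT_LAMBDA_BOUNDS = (-3.0, 3.0)


def boxcox(x, lam: float):
    """Box-Cox transform of positive ``x`` at parameter ``lam``.

    Accepts scalars or arrays; returns the same shape.  Uses ``expm1`` so the
    power branch stays accurate as ``lam -> 0`` and joins the ln branch
    continuously.

    Raises
    ------
    ValueError
        If any value is not strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("Box-Cox transform requires strictly positive values")
    logx = np.log(x)
    if abs(lam) < _LAM_EPS:
        out = logx
    else:
        out = np.expm1(lam * logx) / lam
    if out.ndim == 0:
        return float(out)
    return out


def inverse_boxcox(y, lam: float):
    """Inverse Box-Cox: the positive ``x`` with ``boxcox(x, lam) == y``.

    For ``lam != 0`` the inverse is ``(1 + lam*y)**(1/lam)``, defined only
    when ``1 + lam*y > 0``; outside that domain the limit is not
    representable on the original scale and a :class:`ValueError` is raised.
    ``lam == 1`` is an exact unit shift (``x = y + 1``) and is accepted for
    any ``y``.
    """
    y = np.asarray(y, dtype=float)
    if abs(lam) < _LAM_EPS:
        out = np.exp(y)
    elif lam == 1.0:
        out = y + 1.0
    else:
        base = 1.0 + lam * y
        if np.any(base <= 0):
            raise ValueError(
                "inverse Box-Cox undefined: 1 + lambda*y <= 0 "
                "(limit not representable on the original scale)"
            )
        out = np.exp(np.log(base) / lam)
    if out.ndim == 0:
        return float(out)
    return out


def boxcox_loglik(values: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of ``lam`` for ``values`` (normal theory)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    t = boxcox(values, lam)
    var = float(np.var(t))  # MLE variance (ddof=0)
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lam - 1.0) * float(np.sum(np.log(values)))


@dataclass
class TransformResult:
    """Fitted Box-Cox transform: parameter, likelihood and transformed data."""

    lam: float
    loglik: float
    transformed: np.ndarray = field(repr=False)
    input_min: float

    def inverse(self, y):
        return inverse_boxcox(y, self.lam)


def fit_lambda_mle(
    values,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    xatol: float = 1e-5,
) -> TransformResult:
    """Estimate lambda by maximum likelihood over a bounded interval.

    Parameters
    ----------
    values
        Strictly positive observations, at least 10 of them.
    bounds
        Search interval for lambda.
    xatol
        Absolute tolerance on the fitted lambda.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("insufficient data: Box-Cox MLE needs at least 10 values")
    if np.any(~(values > 0)):
        raise ValueError("Box-Cox MLE requires strictly positive values")

    res = optimize.minimize_scalar(
        lambda lam: -boxcox_loglik(values, lam),
        bounds=bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    lam = float(res.x)
    return TransformResult(
        lam=lam,
        loglik=float(-res.fun),
        transformed=boxcox(values, lam),
        input_min=float(values.min()),
    )
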