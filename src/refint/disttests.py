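"""Skewness/kurtosis coefficients and significance tests.

Used to judge whether a sample is distributed symmetrically — and hence
whether the Box-Cox transformation achieved approximate normality.  The
coefficient of skewness is the moment ratio m3/m2^(3/2) and the coefficient
of kurtosis is the excess kurtosis m4/m2^2 - 3 (0 for a normal sample).
Significance comes from the D'Agostino skewness test and the
Anscombe-Glynn kurtosis test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DistributionTest", "skewness_kurtosis"]


@dataclass
class DistributionTest:
    n: int
    cs: float        # coefficient of skewness, m3 / m2^1.5
    cs_p: float      # D'Agostino skewness-test p-value
    ck: float        # excess kurtosis, m4 / m2^2 - 3
    ck_p: float      # Anscombe-Glynn kurtosis-test p-value
    verdict: str     # "symmetric" or "skewed"


def skewness_kurtosis(values, alpha: float = 0.05) -> DistributionTest:
    """Test whether ``values`` are symmetrically distributed.

    The verdict is "skewed" when the skewness test rejects at level
    ``alpha``, else "symmetric".  Requires n >= 20 (the large-sample
    approximations behind both tests are unreliable below that).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 20:
        raise ValueError("skewness/kurtosis tests need at least 20 values")
    cs = float(stats.skew(values, bias=True))
    ck = float(stats.kurtosis(values, fisher=True, bias=True))
    cs_p = float(stats.skewtest(values).pvalue)
    ck_p = float(stats.kurtosistest(values).pvalue)
    verdict = "skewed" if cs_p < alpha else "symmetric"
    return DistributionTest(n=n, cs=cs, cs_p=cs_p, ck=ck, ck_p=ck_p, verdict=verdict)
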