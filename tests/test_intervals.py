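"""Parametric and non-parametric 95% reference intervals with 90% CIs."""

import math

import numpy as np
import pytest
from scipy import stats

from refint.intervals import (
    build_ri_table,
    nonparametric_ri,
    order_statistic_ci_ranks,
    parametric_ri,
    rank_quantile,
)
from refint.synthetic import SyntheticConfig, generate_cohort
from refint import ingest


def test_rank_quantile_rule_on_1_to_1000():
    values = np.arange(1.0, 1001.0)
    assert rank_quantile(values, 0.025) == pytest.approx(25.025)
    assert rank_quantile(values, 0.975) == pytest.approx(975.975)


def test_nonparametric_limits_on_1_to_1000():
    ri = nonparametric_ri(np.arange(1.0, 1001.0))
    assert ri.lower == pytest.approx(25.025)
    assert ri.upper == pytest.approx(975.975)
    assert ri.lower_ci[0] <= ri.lower <= ri.lower_ci[1]
    assert ri.upper_ci[0] <= ri.upper <= ri.upper_ci[1]
    assert ri.method == "nonparametric" and ri.lam is None


def test_nonparametric_constant_data_degenerate():
    ri = nonparametric_ri(np.full(500, 4.0))
    assert ri.lower == ri.upper == 4.0
    assert ri.lower_ci == (4.0, 4.0) and ri.upper_ci == (4.0, 4.0)


def test_nonparametric_sample_size_gates(rng):
    with pytest.raises(ValueError, match="too small"):
        nonparametric_ri(rng.uniform(1, 2, size=39))
    with pytest.warns(UserWarning, match="n < 120"):
        nonparametric_ri(rng.uniform(1, 2, size=60))


def test_order_statistic_ci_coverage_reaches_conf():
    for n in (120, 500, 5000):
        for p in (0.025, 0.975):
            r, s = order_statistic_ci_ranks(n, p)
            cov = stats.binom.cdf(s - 1, n, p) - stats.binom.cdf(r - 1, n, p)
            assert cov >= 0.90 or (r == 1 and s == n)
            assert 1 <= r < s <= n


def test_nonparametric_monotone_equivariance(rng):
    x = rng.lognormal(4, 0.5, size=800)
    base = nonparametric_ri(x)
    scaled = nonparametric_ri(3.0 * x)
    assert scaled.lower == pytest.approx(3.0 * base.lower)
    assert scaled.upper == pytest.approx(3.0 * base.upper)
    assert scaled.lower_ci[0] == pytest.approx(3.0 * base.lower_ci[0])
    assert scaled.upper_ci[1] == pytest.approx(3.0 * base.upper_ci[1])


def test_parametric_unit_shift_example():
    """Standardized data at lambda=1: limits are -0.96 and 2.96."""
    values = np.array([1.0 - 1.0 / math.sqrt(2), 1.0 + 1.0 / math.sqrt(2)])
    with pytest.warns(UserWarning, match="n < 120"):
        ri = parametric_ri(values, lam=1.0)
    assert ri.lower == pytest.approx(-0.96, abs=1e-9)
    assert ri.upper == pytest.approx(2.96, abs=1e-9)


def test_parametric_recovers_lognormal_percentiles(rng):
    mu, sigma = 4.0, 0.5
    x = rng.lognormal(mu, sigma, size=5000)
    ri = parametric_ri(x)
    assert ri.lower == pytest.approx(math.exp(mu - 1.96 * sigma), rel=0.05)
    assert ri.upper == pytest.approx(math.exp(mu + 1.96 * sigma), rel=0.05)
    assert ri.lower_ci[0] < ri.lower < ri.lower_ci[1]
    assert ri.upper_ci[0] < ri.upper < ri.upper_ci[1]


def test_parametric_lambda_zero_closed_form_large_n(rng):
    mu, sigma = 4.0, 0.6
    x = rng.lognormal(mu, sigma, size=20000)
    ri = parametric_ri(x, lam=0.0)
    assert ri.lower == pytest.approx(math.exp(mu - 1.96 * sigma), rel=0.02)
    assert ri.upper == pytest.approx(math.exp(mu + 1.96 * sigma), rel=0.02)


def test_ci_width_shrinks_with_n(rng):
    widths_par, widths_npar = [], []
    for n in (200, 2000, 20000):
        x = rng.lognormal(4.0, 0.5, size=n)
        p = parametric_ri(x)
        q = nonparametric_ri(x)
        widths_par.append(p.lower_ci[1] - p.lower_ci[0])
        widths_npar.append(q.upper_ci[1] - q.upper_ci[0])
    assert widths_par[0] > widths_par[1] > widths_par[2]
    assert widths_npar[0] > widths_npar[1] > widths_npar[2]


def test_parametric_unrepresentable_limit_reported_not_crashed(rng):
    """Strongly negative lambda can push a limit outside the inverse's domain."""
    x = rng.lognormal(2.0, 1.5, size=500)
    ri = parametric_ri(x, lam=-2.5)
    assert ri.transformed_limits is not None
    if math.isnan(ri.upper) or math.isnan(ri.lower):
        assert ri.notes  # reason recorded


def test_round_values_flag_can_collapse_ci(rng):
    # heavily discretised data: whole-unit reporting near the lower limit
    x = np.round(rng.lognormal(2.0, 0.8, size=2000))
    x = x[x > 0]
    ri = nonparametric_ri(x, round_values=True)
    assert float(ri.lower).is_integer()


def _clean_frame(n_per_group, seed):
    frame, _ = generate_cohort(SyntheticConfig(n_per_group=n_per_group, seed=seed))
    cleaned, _ = ingest.clean(ingest.parse_raw_frame(frame))
    return cleaned


def test_build_ri_table_structure():
    table = build_ri_table(_clean_frame(700, seed=5))
    names = [g.name for g in table]
    assert names == ["males", "all_females", "females_lt_50", "females_ge_50"]
    for grp in table:
        assert grp.parametric.method == "parametric"
        assert grp.nonparametric.method == "nonparametric"
        assert grp.outliers.converged
        assert grp.dist_before.verdict == "skewed"
        assert grp.dist_after_transformed.verdict == "symmetric"


def test_build_ri_table_male_only_input():
    cleaned = _clean_frame(700, seed=6)
    males_only = cleaned.loc[cleaned["sex"] == "male"]
    table = build_ri_table(males_only)
    assert [g.name for g in table] == ["males"]


def test_build_ri_table_no_split_pools_everything():
    cleaned = _clean_frame(400, seed=7)
    table = build_ri_table(cleaned, sex_split=False)
    assert [g.name for g in table] == ["all"]
    assert table[0].n == len(cleaned)
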