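"""Cohort generator: determinism, planted truth, and emulated artifacts."""

import math

import numpy as np
import pandas as pd
import pytest

from refint import ingest
from refint.partition import spearman_rho
from refint.synthetic import (
    STRATA,
    Stratum,
    SyntheticConfig,
    generate_cohort,
    write_cohort,
)


def test_same_seed_byte_identical_csv(tmp_path):
    cfg = SyntheticConfig(n_per_group=300, seed=42)
    paths = []
    for i in (1, 2):
        frame, truth = generate_cohort(cfg)
        p = tmp_path / f"c{i}.csv"
        write_cohort(frame, truth, p, tmp_path / f"t{i}.json")
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    assert (tmp_path / "t1.json").read_bytes() == (tmp_path / "t2.json").read_bytes()


def test_different_seed_different_bytes(tmp_path):
    for i, seed in enumerate((1, 2)):
        frame, truth = generate_cohort(SyntheticConfig(n_per_group=300, seed=seed))
        write_cohort(frame, truth, tmp_path / f"c{i}.csv")
    assert (tmp_path / "c0.csv").read_bytes() != (tmp_path / "c1.csv").read_bytes()


def test_invalid_configs_rejected_before_generation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_per_group=0).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(contamination_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(age_range=(10, 90)).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(censor_limits=(2000.0, 1.0)).validate()


def test_clean_cohort_identity_without_artifacts():
    cfg = SyntheticConfig(n_per_group=400, seed=9, contamination_fraction=0.0,
                          duplicate_rate=0.0, missing_rate=0.0)
    frame, truth = generate_cohort(cfg)
    cleaned, report = ingest.clean(ingest.parse_raw_frame(frame))
    assert report.n_excluded == truth.censored_count == 0
    assert len(cleaned) == len(frame) == truth.n_raw


def test_truth_percentiles_match_monte_carlo(rng):
    cfg = SyntheticConfig()
    _, truth = generate_cohort(SyntheticConfig(n_per_group=50, seed=1))
    for name in STRATA:
        st = cfg.strata[name]
        draws = rng.lognormal(st.mu, st.sigma, size=1_000_000)
        mc = np.quantile(draws, [0.025, 0.975])
        tl, tu = truth.true_percentiles[name]
        assert tl == pytest.approx(mc[0], rel=0.01)
        assert tu == pytest.approx(mc[1], rel=0.01)


def test_stratum_sample_medians_converge():
    cfg = SyntheticConfig(n_per_group=10_000, seed=13, contamination_fraction=0.0,
                          duplicate_rate=0.0, missing_rate=0.0)
    frame, truth = generate_cohort(cfg)
    df = ingest.parse_raw_frame(frame)
    males = df.loc[df["sex"] == "male", "value"]
    assert np.median(males) == pytest.approx(truth.stratum_medians["male"], rel=0.02)
    young = df.loc[(df["sex"] == "female") & (df["age"] < 50), "value"]
    assert np.median(young) == pytest.approx(
        truth.stratum_medians["female_young"], rel=0.02)


def test_female_age_trend_is_planted():
    frame, _ = generate_cohort(SyntheticConfig(n_per_group=3000, seed=2))
    df = ingest.parse_raw_frame(frame)
    cleaned, _ = ingest.clean(df)
    females = cleaned.loc[cleaned["sex"] == "female"]
    res = spearman_rho(females["age"].to_numpy(float),
                       females["value"].to_numpy(float))
    assert res.rho > 0.3 and res.p < 1e-6


def test_contaminated_rows_are_extreme(small_cohort):
    cfg, frame, truth = small_cohort
    rows = frame.iloc[truth.contaminated_rows]
    ages = pd.to_numeric(rows["age"], errors="coerce")
    rows = rows.loc[ages.notna() & (rows["sex"] != "")]  # demographics intact
    values = rows["value"].astype(float).to_numpy()
    strata = np.where(rows["sex"] == "male", "male",
                      np.where(ages.loc[rows.index] < cfg.female_age_break,
                               "female_young", "female_old"))
    lo = np.array([cfg.strata[s].percentiles()[0] for s in strata])
    hi = np.array([cfg.strata[s].percentiles()[1] for s in strata])
    # planted contaminants concentrate outside their stratum's healthy band
    frac_outside = np.mean((values < lo) | (values > hi))
    assert frac_outside > 0.8


def test_stratum_percentile_closed_form():
    st = Stratum(mu=math.log(100.0), sigma=0.5)
    lo, hi = st.percentiles()
    assert lo == pytest.approx(100.0 * math.exp(-1.96 * 0.5))
    assert hi == pytest.approx(100.0 * math.exp(1.96 * 0.5))
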