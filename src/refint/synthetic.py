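"""Synthetic ferritin-like cohorts with known ground truth.

Emulates a health-examination serum-ferritin extract: right-skewed positive
values (lognormal within each stratum), a large male/female difference, an
upward shift in females from the configured age break (the post-menopausal
rise), a small disease-like contaminated fraction in both tails (iron
deficiency low, overload/inflammation high), plus the raw-file artifacts a
LIS export carries — values outside the assay's reportable range, repeat
visits per subject, and records with missing demographics.  The generator
never cleans anything itself: artifacts are written into the raw table for
the ingest module to deal with, and a :class:`CohortTruth` side-object
records exactly what was planted so every pipeline stage can be tested
against known truth.

Default stratum parameters place the group medians near 190 (males), 45
(females below the age break) and 90 ug/L (females at or above it), with
log-scale spreads of 0.55/0.80/0.70 — geometric SDs of roughly 1.7-2.2,
typical of ferritin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["Stratum", "SyntheticConfig", "CohortTruth", "generate_cohort", "write_cohort"]

STRATA = ("male", "female_young", "female_old")

_DATE_START = np.datetime64("2010-12-01")
_DATE_END = np.datetime64("2019-04-30")


@dataclass(frozen=True)
class Stratum:
    """Lognormal parameters of one healthy stratum (log-ug/L)."""

    mu: float
    sigma: float

    def percentiles(self, z: float = 1.96) -> tuple[float, float]:
        """Closed-form central-95% bounds exp(mu -/+ z*sigma)."""
        return math.exp(self.mu - z * self.sigma), math.exp(self.mu + z * self.sigma)


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_per_group: int = 5000          # records per sex before artifacts
    sex_mix: float = 0.5             # proportion male of the 2*n_per_group total
    age_range: tuple[int, int] = (18, 90)
    female_age_break: int = 50
    strata: dict = field(default_factory=lambda: {
        "male": Stratum(mu=math.log(190.0), sigma=0.55),
        "female_young": Stratum(mu=math.log(45.0), sigma=0.80),
        "female_old": Stratum(mu=math.log(90.0), sigma=0.70),
    })
    contamination_fraction: float = 0.02
    low_tail_fraction: float = 0.5   # share of contaminants in the deficiency tail
    low_tail_scale: float = 0.04     # multiplies a healthy draw into the deficiency range
    high_tail_scale: float = 8.0     # multiplies a healthy draw into the overload range
    censor_limits: tuple[float, float] = (1.0, 2000.0)
    duplicate_rate: float = 0.03     # extra later visits, as a fraction of subjects
    missing_rate: float = 0.02       # records with sex or age blanked
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        for name, p in (("sex_mix", self.sex_mix),
                        ("contamination_fraction", self.contamination_fraction),
                        ("low_tail_fraction", self.low_tail_fraction),
                        ("duplicate_rate", self.duplicate_rate),
                        ("missing_rate", self.missing_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        lo, hi = self.age_range
        if not (18 <= lo < hi <= 95):
            raise ValueError("age_range must be increasing and within [18, 95]")
        if not 18 <= self.female_age_break <= 95:
            raise ValueError("female_age_break outside the supported age span")
        for name in STRATA:
            st = self.strata[name]
            if st.sigma <= 0:
                raise ValueError(f"stratum {name}: sigma must be positive")
        if not self.censor_limits[0] < self.censor_limits[1]:
            raise ValueError("censor_limits must be increasing")
        if self.low_tail_scale <= 0 or self.high_tail_scale <= 0:
            raise ValueError("contamination scales must be positive")


@dataclass
class CohortTruth:
    """What the generator planted, for truth-based testing."""

    true_percentiles: dict            # stratum -> (2.5th, 97.5th) of the healthy component
    stratum_medians: dict             # stratum -> exp(mu)
    contaminated_rows: list           # row positions (0-based, raw file order)
    duplicate_rows: list              # injected repeat-visit row positions
    missing_rows: list                # row positions with blanked demographics
    censored_count: int               # raw values outside the censor limits
    n_raw: int
    n_base: int                       # subjects, before artifact injection

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(asdict(self), **kwargs)


def _draw_dates(rng: np.random.Generator, n: int) -> np.ndarray:
    span = int((_DATE_END - _DATE_START) / np.timedelta64(1, "D"))
    return _DATE_START + rng.integers(0, span + 1, size=n).astype("timedelta64[D]")


def _stratum_of(sex: np.ndarray, age: np.ndarray, age_break: int) -> np.ndarray:
    out = np.where(sex == "male", "male",
                   np.where(age < age_break, "female_young", "female_old"))
    return out.astype(object)


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a raw cohort table and its ground truth.

    The same seed and config always produce an identical table (and hence
    byte-identical CSV via :func:`write_cohort`).  Values are reported at
    0.01 ug/L resolution, like an assay printout.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.censor_limits

    n_total = 2 * cfg.n_per_group
    n_male = int(round(cfg.sex_mix * n_total))
    n_female = n_total - n_male
    sex = np.array(["male"] * n_male + ["female"] * n_female, dtype=object)
    age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n_total)
    stratum = _stratum_of(sex, age, cfg.female_age_break)

    mu = np.array([cfg.strata[s].mu for s in stratum])
    sigma = np.array([cfg.strata[s].sigma for s in stratum])
    value = rng.lognormal(mean=mu, sigma=sigma)

    # plant disease-like contamination in both tails
    k_cont = int(round(cfg.contamination_fraction * n_total))
    cont_rows = rng.choice(n_total, size=k_cont, replace=False)
    k_low = int(round(cfg.low_tail_fraction * k_cont))
    value[cont_rows[:k_low]] *= cfg.low_tail_scale
    value[cont_rows[k_low:]] *= cfg.high_tail_scale

    value = np.round(value, 2)  # assay reporting resolution
    subject_id = np.array([f"S{i:06d}" for i in range(n_total)], dtype=object)
    dates = _draw_dates(rng, n_total)

    in_limits = (value >= low) & (value <= high)
    censored_count = int(n_total - in_limits.sum())

    # blank demographics on a sample of in-range rows (so the missing-field
    # rule, not the detection-limit rule, is what removes them)
    k_miss = int(round(cfg.missing_rate * n_total))
    eligible = np.flatnonzero(in_limits)
    miss_rows = rng.choice(eligible, size=min(k_miss, eligible.size), replace=False)

    # inject repeat visits: a later-dated, in-range, fully complete record
    # for subjects not already carrying blanked demographics
    k_dup = int(round(cfg.duplicate_rate * n_total))
    dup_eligible = np.setdiff1d(eligible, miss_rows)
    dup_src = rng.choice(dup_eligible, size=min(k_dup, dup_eligible.size), replace=False)
    dup_frames = []
    for pos, src in enumerate(dup_src):
        st = cfg.strata[stratum[src]]
        v = np.round(rng.lognormal(st.mu, st.sigma), 2)
        while not (low <= v <= high):
            v = np.round(rng.lognormal(st.mu, st.sigma), 2)
        dup_frames.append((subject_id[src], sex[src], int(age[src]), v,
                           dates[src] + np.timedelta64(int(rng.integers(30, 400)), "D")))

    sex_out = sex.copy()
    age_out = age.astype(object)
    for r in miss_rows:
        if rng.random() < 0.5:
            sex_out[r] = ""
        else:
            age_out[r] = ""

    frame = pd.DataFrame({
        "subject_id": subject_id,
        "sex": sex_out,
        "age": age_out,
        "value": value,
        "date": dates,
    })
    if dup_frames:
        dup_df = pd.DataFrame(dup_frames, columns=frame.columns)
        frame = pd.concat([frame, dup_df], ignore_index=True)
    frame["date"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d")
    frame["value"] = frame["value"].map(lambda v: f"{v:.2f}")

    truth = CohortTruth(
        true_percentiles={s: cfg.strata[s].percentiles() for s in STRATA},
        stratum_medians={s: math.exp(cfg.strata[s].mu) for s in STRATA},
        contaminated_rows=sorted(int(r) for r in cont_rows),
        duplicate_rows=list(range(n_total, n_total + len(dup_frames))),
        missing_rows=sorted(int(r) for r in miss_rows),
        censored_count=censored_count,
        n_raw=len(frame),
        n_base=n_total,
    )
    return frame, truth


def write_cohort(frame: pd.DataFrame, truth: CohortTruth, csv_path, truth_path=None) -> None:
    """Write the raw CSV (deterministic bytes) and optional truth JSON."""
    frame.to_csv(csv_path, index=False, lineterminator="\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(truth.to_json())
            fh.write("\n")
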