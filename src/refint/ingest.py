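"""Reading raw laboratory extracts and applying the exclusion rules.

A routine laboratory-information-system export is cleaned in a fixed order:

1. pregnant subjects (optional boolean column; ignored when absent),
2. values censored by the assay's reportable range (strictly below ``low``
   or strictly above ``high``; values exactly at a limit are retained),
3. records with missing demographics (sex, age) or an unparseable value,
4. duplicate visits — only the FIRST result per subject (earliest
   collection date, earlier file row on ties) is retained.

Each excluded record is counted under the first rule that removes it, so
the counters decompose the total exclusion while the retained count is
order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "AnalyteRecord",
    "CleaningReport",
    "load_records",
    "parse_raw_frame",
    "apply_detection_limits",
    "drop_incomplete",
    "deduplicate_first",
    "clean",
]

CANONICAL_COLUMNS = ("subject_id", "sex", "age", "value", "date")

_SEX_CODES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}


@dataclass(frozen=True)
class AnalyteRecord:
    """One laboratory result: who, what, when.

    The tabular pipeline carries these as DataFrame rows; the dataclass is
    the row contract (missing fields appear as None/NaN until cleaning).
    """

    subject_id: str
    sex: str | None       # "male" / "female" / None when missing or unknown code
    age: int | None       # integer years (truncated on ingest)
    value: float | None   # ug/L, > 0 when present
    date: object | None   # datetime.date / pandas Timestamp


def load_records(
    path,
    columns: dict[str, str] | None = None,
    pregnant_column: str | None = None,
) -> pd.DataFrame:
    """Read a CSV of analyte results into the canonical frame.

    ``columns`` maps canonical names (``subject_id``, ``sex``, ``age``,
    ``value``, ``date``) to the file's header names; identity by default.
    Unparseable value/age/date cells and unknown sex codes become missing
    fields — the rows are KEPT so that :func:`drop_incomplete` can count
    them.  An optional boolean ``pregnant_column`` is carried through for
    the eligibility filter.
    """
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if columns:
        colmap.update(columns)
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    except Exception as exc:  # malformed CSV
        raise ValueError(f"could not parse input file {path}: {exc}") from exc

    try:
        return parse_raw_frame(raw, columns=columns, pregnant_column=pregnant_column)
    except ValueError as exc:
        raise ValueError(f"input file {path}: {exc}") from exc


def parse_raw_frame(
    raw: pd.DataFrame,
    columns: dict[str, str] | None = None,
    pregnant_column: str | None = None,
) -> pd.DataFrame:
    """Coerce a raw tabular frame (strings allowed) into the canonical frame.

    Same parsing rules as :func:`load_records`; useful when the raw table is
    already in memory (e.g. straight from the synthetic generator).
    """
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if columns:
        colmap.update(columns)
    missing_cols = [v for v in colmap.values() if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {', '.join(missing_cols)}")

    df = pd.DataFrame(index=raw.index)
    df["subject_id"] = raw[colmap["subject_id"]].astype("string").str.strip()
    df.loc[df["subject_id"] == "", "subject_id"] = pd.NA
    sex = raw[colmap["sex"]].astype("string").str.strip().str.lower()
    df["sex"] = sex.map(_SEX_CODES).astype("string")
    # age truncated to integer years
    age = pd.to_numeric(raw[colmap["age"]].astype("string"), errors="coerce")
    df["age"] = np.floor(age).astype("Int64")
    df["value"] = pd.to_numeric(raw[colmap["value"]].astype("string"), errors="coerce")
    df["date"] = pd.to_datetime(
        raw[colmap["date"]].astype("string"), errors="coerce", format="ISO8601"
    )
    if pregnant_column is not None and pregnant_column in raw.columns:
        preg = raw[pregnant_column].astype("string").str.strip().str.lower()
        df["pregnant"] = preg.isin(("1", "true", "yes", "y"))
    return df


def apply_detection_limits(
    records: pd.DataFrame, low: float = 1.0, high: float = 2000.0
) -> tuple[pd.DataFrame, int]:
    """Drop values strictly outside the assay's reportable range.

    Boundary values (exactly ``low`` or ``high``) are retained.  Missing
    values pass through — they are the missing-field filter's business.
    Returns ``(retained, n_excluded)``.
    """
    if not low < high:
        raise ValueError("detection limits must satisfy low < high")
    value = records["value"]
    outside = value.notna() & ((value < low) | (value > high))
    return records.loc[~outside], int(outside.sum())


def drop_incomplete(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records missing sex, age or value; returns ``(retained, n_dropped)``."""
    incomplete = (
        records["sex"].isna() | records["age"].isna() | records["value"].isna()
    )
    return records.loc[~incomplete], int(incomplete.sum())


def deduplicate_first(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep only the first result per subject.

    "First" means earliest collection date; ties (and missing dates, which
    sort last) are broken by file order, earlier row winning.  Records with
    a missing subject id are treated as distinct subjects and all kept.
    Returns ``(retained, n_removed)``.
    """
    known = records["subject_id"].notna()
    dated = records.loc[known]
    # stable sort: earliest date first, NaT last; original order breaks ties
    order = dated.sort_values("date", kind="stable", na_position="last")
    keep_idx = order.drop_duplicates(subset="subject_id", keep="first").index
    removed = len(dated) - len(keep_idx)
    retained = records.loc[records.index.isin(keep_idx) | ~known]
    return retained, int(removed)


@dataclass
class CleaningReport:
    """Tally of the exclusion rules; counters are attribute-first-rule."""

    n_raw: int = 0
    n_pregnant: int = 0
    n_out_of_limits: int = 0
    n_missing_demographics: int = 0
    n_duplicates_removed: int = 0
    by_sex: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return (self.n_pregnant + self.n_out_of_limits
                + self.n_missing_demographics + self.n_duplicates_removed)

    @property
    def n_retained(self) -> int:
        return self.n_raw - self.n_excluded

    @property
    def percent_excluded(self) -> float:
        """Exclusions as a percentage of raw records, 2 decimals."""
        if self.n_raw == 0:
            return 0.0
        return round(100.0 * self.n_excluded / self.n_raw, 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_excluded"] = self.n_excluded
        d["n_retained"] = self.n_retained
        d["percent_excluded"] = self.percent_excluded
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [
            f"raw records:            {self.n_raw}",
            f"  pregnant excluded:    {self.n_pregnant}",
            f"  outside limits:       {self.n_out_of_limits}",
            f"  missing demographics: {self.n_missing_demographics}",
            f"  duplicate results:    {self.n_duplicates_removed}",
            f"retained:               {self.n_retained} "
            f"({self.percent_excluded}% excluded)",
        ]
        return "\n".join(lines)


def _sex_keys(sex: pd.Series) -> pd.Series:
    """Map a sex column to counter buckets ('unknown' for missing/odd codes)."""
    return sex.where(sex.isin(("male", "female")), "unknown").astype(object)


def clean(
    records: pd.DataFrame,
    low: float = 1.0,
    high: float = 2000.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply all exclusion rules in order; returns the clean frame + tally.

    Idempotent: running the cleaner on its own output changes nothing.
    Per-sex counters (with an "unknown" bucket for records whose sex is
    itself missing) sum exactly to the overall counters.
    """
    report = CleaningReport(n_raw=len(records))
    sexes = ["male", "female", "unknown"]
    per_sex = {s: {"n_raw": 0, "n_pregnant": 0, "n_out_of_limits": 0,
                   "n_missing_demographics": 0, "n_duplicates_removed": 0,
                   "n_retained": 0} for s in sexes}
    sex_of = _sex_keys(records["sex"]) if len(records) else pd.Series(dtype=object)
    for s in sex_of:
        per_sex[s]["n_raw"] += 1

    def count(mask_index, counter):
        for s in sex_of.loc[mask_index]:
            per_sex[s][counter] += 1

    current = records
    if "pregnant" in current.columns:
        preg = current["pregnant"].fillna(False).astype(bool)
        report.n_pregnant = int(preg.sum())
        count(current.index[preg], "n_pregnant")
        current = current.loc[~preg]

    before = current.index
    current, report.n_out_of_limits = apply_detection_limits(current, low, high)
    count(before.difference(current.index), "n_out_of_limits")

    before = current.index
    current, report.n_missing_demographics = drop_incomplete(current)
    count(before.difference(current.index), "n_missing_demographics")

    before = current.index
    current, report.n_duplicates_removed = deduplicate_first(current)
    count(before.difference(current.index), "n_duplicates_removed")

    for s in (sex_of.loc[current.index] if len(current) else []):
        per_sex[s]["n_retained"] += 1
    report.by_sex = per_sex
    assert report.n_retained == len(current)
    return current, report
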