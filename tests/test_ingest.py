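"""Cleaning rules: detection limits, missing fields, first-result dedup."""

import numpy as np
import pandas as pd
import pytest

from refint import ingest
from refint.synthetic import SyntheticConfig, generate_cohort, write_cohort


def test_load_records_parses_and_flags_missing_fields(tmp_path, tiny_raw_frame):
    path = tmp_path / "raw.csv"
    tiny_raw_frame.to_csv(path, index=False)
    df = ingest.load_records(path)
    assert len(df) == len(tiny_raw_frame)
    # sex codes normalised; unknown code and empty cell become missing
    assert list(df["sex"].fillna("?")) == [
        "male", "female", "female", "male", "?", "?", "female"]
    # age truncated to integer years; empty cell missing
    assert df.loc[1, "age"] == 35
    assert pd.isna(df.loc[2, "age"])
    # unparseable value kept as a missing field, not dropped
    assert pd.isna(df.loc[6, "value"])


def test_load_records_missing_file_and_missing_column(tmp_path):
    with pytest.raises(FileNotFoundError, match="nope.csv"):
        ingest.load_records(tmp_path / "nope.csv")
    path = tmp_path / "short.csv"
    pd.DataFrame({"subject_id": ["a"], "value": [1.0]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="sex"):
        ingest.load_records(path)


def test_load_records_column_mapping(tmp_path, tiny_raw_frame):
    renamed = tiny_raw_frame.rename(columns={"value": "ferritin", "sex": "gender"})
    path = tmp_path / "mapped.csv"
    renamed.to_csv(path, index=False)
    df = ingest.load_records(path, columns={"value": "ferritin", "sex": "gender"})
    assert df.loc[0, "value"] == 150.5


def test_detection_limits_boundary_semantics():
    df = pd.DataFrame({"value": [0.99, 1.0, 1500.0, 2000.0, 2000.01]})
    kept, excluded = ingest.apply_detection_limits(df, 1.0, 2000.0)
    assert list(kept["value"]) == [1.0, 1500.0, 2000.0]
    assert excluded == 2
    kept_all, none_excluded = ingest.apply_detection_limits(kept, 1.0, 2000.0)
    assert none_excluded == 0 and len(kept_all) == 3
    with pytest.raises(ValueError):
        ingest.apply_detection_limits(df, 5.0, 5.0)


def test_detection_limits_empty_input():
    kept, excluded = ingest.apply_detection_limits(pd.DataFrame({"value": []}), 1, 2000)
    assert len(kept) == 0 and excluded == 0


def test_deduplicate_keeps_earliest_date_then_row_order(tiny_raw_frame):
    df = ingest.parse_raw_frame(tiny_raw_frame)
    kept, removed = ingest.deduplicate_first(df)
    assert removed == 1
    # subject A appears twice; the 2011 visit (later row) wins on date
    a = kept.loc[kept["subject_id"] == "A"]
    assert len(a) == 1 and a.iloc[0]["date"] == pd.Timestamp("2011-03-02")
    # date tie broken by file order
    tie = pd.DataFrame({
        "subject_id": ["X", "X"], "sex": ["male", "male"], "age": [30, 30],
        "value": [10.0, 20.0], "date": pd.to_datetime(["2012-01-01", "2012-01-01"]),
    })
    kept_tie, _ = ingest.deduplicate_first(tie)
    assert kept_tie.iloc[0]["value"] == 10.0


def test_deduplicate_identity_when_all_unique(tiny_raw_frame):
    df = ingest.parse_raw_frame(tiny_raw_frame).drop(index=3)
    kept, removed = ingest.deduplicate_first(df)
    assert removed == 0 and kept.equals(df)


def test_drop_incomplete(tiny_raw_frame):
    df = ingest.parse_raw_frame(tiny_raw_frame)
    kept, dropped = ingest.drop_incomplete(df)
    # rows 2 (no age), 4 (no sex), 5 (unknown sex), 6 (bad value) go
    assert dropped == 4
    assert set(kept["subject_id"]) == {"A", "B"}


def test_clean_conservation_and_per_sex_decomposition(small_cohort):
    _, frame, truth = small_cohort
    df = ingest.parse_raw_frame(frame)
    cleaned, report = ingest.clean(df)
    assert report.n_raw == truth.n_raw
    assert report.n_retained == len(cleaned)
    assert report.n_raw == report.n_retained + report.n_excluded
    for counter in ("n_raw", "n_out_of_limits", "n_missing_demographics",
                    "n_duplicates_removed", "n_retained"):
        total = sum(report.by_sex[s][counter] for s in report.by_sex)
        overall = getattr(report, counter) if counter != "n_raw" else report.n_raw
        assert total == overall, counter


def test_clean_counters_match_generator_truth(small_cohort):
    _, frame, truth = small_cohort
    cleaned, report = ingest.clean(ingest.parse_raw_frame(frame))
    assert report.n_out_of_limits == truth.censored_count
    assert report.n_missing_demographics == len(truth.missing_rows)
    assert report.n_duplicates_removed == len(truth.duplicate_rows)
    # one record per surviving subject
    assert cleaned["subject_id"].is_unique


def test_clean_is_idempotent(small_cohort):
    _, frame, _ = small_cohort
    once, rep1 = ingest.clean(ingest.parse_raw_frame(frame))
    twice, rep2 = ingest.clean(once)
    assert rep2.n_excluded == 0
    assert twice.equals(once)


def test_pregnant_column_filter(tmp_path):
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c"], "sex": ["F", "F", "F"],
        "age": [30, 31, 32], "value": [50.0, 60.0, 70.0],
        "date": ["2015-01-01", "2015-01-02", "2015-01-03"],
        "pregnant": ["yes", "no", ""],
    })
    path = tmp_path / "p.csv"
    df.to_csv(path, index=False)
    records = ingest.load_records(path, pregnant_column="pregnant")
    cleaned, report = ingest.clean(records)
    assert report.n_pregnant == 1
    assert set(cleaned["subject_id"]) == {"b", "c"}


def test_round_trip_row_count_against_generator_manifest(tmp_path):
    cfg = SyntheticConfig(n_per_group=200, seed=3)
    frame, truth = generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(frame, truth, path)
    df = ingest.load_records(path)
    assert len(df) == truth.n_raw


def test_cleaning_report_serialization():
    report = ingest.CleaningReport(n_raw=10, n_out_of_limits=2,
                                   n_missing_demographics=1, n_duplicates_removed=3)
    d = report.to_dict()
    assert d["n_retained"] == 4 and d["n_excluded"] == 6
    assert "retained" in report.to_text()
    assert '"n_retained": 4' in report.to_json()
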