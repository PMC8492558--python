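"""Dialect detection, normalization, exclusion accounting and validation."""

import pandas as pd
import pytest

from edish.config import ConfigurationError, DataValidationError, EdishConfig
from edish.ingest import (
    MappingConfig,
    detect_dialect,
    normalize,
    read_table,
    validate,
)
from edish.synthetic import SimSpec, simulate_study, write_dialect

IDENTITY = MappingConfig(subject_id="subj", analyte_code="test",
                         result_value="result", uln_value="uln", study_day="day")


def raw(rows, columns=("subj", "test", "result", "uln", "day")):
    return pd.DataFrame(rows, columns=list(columns))


@pytest.mark.parametrize("columns, expected", [
    (["USUBJID", "LBTESTCD", "LBSTRESN", "LBSTNRHI", "LBDY"], "sdtm"),
    (["USUBJID", "PARAMCD", "AVAL", "ANRHI", "ADY"], "adam"),
    (["USUBJID", "PARAMCD", "AVAL", "A1HI", "ADY"], "adam"),
    (["id", "test", "result"], "unknown"),
    (["USUBJID", "LBTESTCD", "LBSTRESN", "LBSTNRHI", "LBDY",
      "PARAMCD", "AVAL", "ANRHI", "ADY"], "adam"),  # tie prefers ADaM
])
def test_detect_dialect(columns, expected):
    df = pd.DataFrame([["x"] * len(columns)], columns=columns)
    assert detect_dialect(df) == expected


def test_detect_dialect_empty_input():
    with pytest.raises(DataValidationError, match="empty input"):
        detect_dialect(pd.DataFrame())


def test_normalize_identity_mapping():
    study = normalize(raw([("S01", "ALT", 120, 40, 8), ("S01", "BILI", 2.5, 1.2, 8)]),
                      IDENTITY)
    rec = study.records
    assert len(rec) == 2
    alt = rec[rec["analyte"] == "ALT"].iloc[0]
    assert (alt["subject_id"], alt["value"], alt["uln"], alt["study_day"]) == \
        ("S01", 120.0, 40.0, 8)
    assert set(rec["analyte"]) == {"ALT", "TB"}


def test_non_numeric_result_excluded_and_counted():
    study = normalize(raw([("S01", "ALT", "NQ", 40, 8), ("S01", "ALT", 120, 40, 15),
                           ("S01", "BILI", 1.0, 1.2, 15)]), IDENTITY)
    assert study.exclusions["non_numeric_result"] == 1
    assert len(study.records) == 2


def test_unmapped_analyte_excluded_not_silently_dropped():
    study = normalize(raw([("S01", "GGT", 99, 50, 8), ("S01", "ALT", 120, 40, 8),
                           ("S01", "BILI", 1.0, 1.2, 8)]), IDENTITY)
    assert study.exclusions["unmapped_analyte"] == 1
    assert any("unmapped_analyte" in w for w in study.warnings)


def test_dedup_policy_max_keeps_largest():
    study = normalize(raw([("S01", "ALT", 100, 40, 8), ("S01", "ALT", 110, 40, 8),
                           ("S01", "BILI", 1.0, 1.2, 8)]), IDENTITY)
    alt = study.records[study.records["analyte"] == "ALT"]
    assert len(alt) == 1 and alt.iloc[0]["value"] == 110.0
    assert study.exclusions["duplicate_collapsed"] == 1


@pytest.mark.parametrize("policy, expected", [("first", 100.0), ("mean", 105.0)])
def test_dedup_policy_configurable(policy, expected):
    cfg = EdishConfig(dedup_policy=policy)
    study = normalize(raw([("S01", "ALT", 100, 40, 8), ("S01", "ALT", 110, 40, 8),
                           ("S01", "BILI", 1.0, 1.2, 8)]), IDENTITY, cfg)
    assert study.records[study.records["analyte"] == "ALT"].iloc[0]["value"] == expected


def test_missing_uln_falls_back_to_study_uln_else_excluded():
    rows = [("S01", "ALT", 120, "", 8), ("S01", "BILI", 2.0, 1.2, 8)]
    with_fallback = normalize(raw(rows), IDENTITY, EdishConfig(study_uln={"ALT": 40.0}))
    alt = with_fallback.records[with_fallback.records["analyte"] == "ALT"]
    assert alt.iloc[0]["uln"] == 40.0
    without = normalize(raw(rows + [("S01", "ALT", 100, 40, 15)]), IDENTITY)
    assert without.exclusions["missing_uln"] == 1


def test_day_zero_and_negative_values_excluded():
    study = normalize(raw([("S01", "ALT", 120, 40, 0), ("S01", "ALT", -5, 40, 8),
                           ("S01", "ALT", 120, 40, 8), ("S01", "BILI", 1.0, 1.2, 8)]),
                      IDENTITY)
    assert study.exclusions["invalid_study_day"] == 1
    assert study.exclusions["negative_result"] == 1
    assert len(study.records) == 2


def test_missing_required_binding_named():
    df = raw([("S01", "ALT", 120, 40, 8)]).drop(columns=["uln"])
    with pytest.raises(ConfigurationError, match="uln_value"):
        normalize(df, IDENTITY)


def test_zero_evaluable_subjects_is_an_error():
    # only baseline-day records: no post-baseline ALT/TB anywhere
    with pytest.raises(DataValidationError, match="zero evaluable"):
        normalize(raw([("S01", "ALT", 30, 40, 1), ("S01", "BILI", 0.5, 1.2, 1)]),
                  IDENTITY)


def test_uln_variability_warning():
    study = normalize(raw([("S01", "ALT", 120, 40, 8), ("S02", "ALT", 120, 100, 8),
                           ("S01", "BILI", 1.0, 1.2, 8), ("S02", "BILI", 1.0, 1.2, 8)]),
                      IDENTITY)
    assert any("varies more than 2x" in w for w in study.warnings)


def test_exclusion_accounting_conserves_rows():
    rows = [("S01", "ALT", 120, 40, 8), ("S01", "ALT", "NQ", 40, 15),
            ("S01", "GGT", 9, 50, 8), ("S01", "ALT", 125, 40, 8),
            ("S01", "BILI", 1.0, 1.2, 8)]
    study = normalize(raw(rows), IDENTITY)
    accounted = len(study.records) + sum(study.exclusions.values())
    assert accounted == len(rows)


def test_validation_report_counts():
    study = normalize(raw([("S01", "ALT", 120, 40, 8), ("S01", "BILI", 1.0, 1.2, 8),
                           ("S02", "ALT", 120, 40, 8)]), IDENTITY)
    report = validate(study)
    assert report.n_subjects == 2
    assert report.n_evaluable == 1
    assert report.non_evaluable == {"S02": "no post-baseline TB"}
    assert report.n_evaluable + report.n_non_evaluable == report.n_subjects


def test_validate_simulated_study_all_evaluable():
    study, _ = simulate_study(SimSpec(n_subjects=100, seed=5))
    report = validate(study)
    # independent direct scan over raw records
    post = study.records[study.records["study_day"] > 1]
    n_eval = sum(
        1 for sid in study.subjects()
        if not post[(post["subject_id"] == sid) & (post["analyte"] == "ALT")].empty
        and not post[(post["subject_id"] == sid) & (post["analyte"] == "TB")].empty)
    assert report.n_evaluable == n_eval == 100


def test_round_trip_both_dialects_equal(tmp_path, small_noisy_study):
    study, _ = small_noisy_study
    p_sdtm = write_dialect(study, "sdtm", tmp_path / "lab_sdtm.csv")
    p_adam = write_dialect(study, "adam", tmp_path / "lab_adam.csv")
    s1 = normalize(read_table(p_sdtm))
    s2 = normalize(read_table(p_adam))
    assert s1.records.equals(s2.records)
    assert s1.records.equals(study.records)
    assert s1.provenance["dialect"] == "sdtm"
    assert s2.provenance["dialect"] == "adam"


def test_normalize_idempotent(tmp_path, small_noisy_study):
    study, _ = small_noisy_study
    path = write_dialect(study, "sdtm", tmp_path / "a.csv")
    once = normalize(read_table(path))
    path2 = write_dialect(once, "sdtm", tmp_path / "b.csv")
    twice = normalize(read_table(path2))
    assert once.records.equals(twice.records)


def test_read_table_sniffs_tab_delimiter(tmp_path):
    path = tmp_path / "lab.tsv"
    path.write_text("subj\ttest\tresult\tuln\tday\nS01\tALT\t120\t40\t8\n"
                    "S01\tBILI\t1.0\t1.2\t8\n")
    study = normalize(read_table(path), IDENTITY)
    assert len(study.records) == 2
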