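"""Fold normalization, R/nR ratios, peaks, P_ALT, pattern and hysteresis."""

import copy
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assert_matches_oracle, brute_force_summary, make_study
from edish.config import EdishConfig, PAltConstants
from edish.derive import (
    compute_visit_derived,
    fold_baseline,
    fold_uln,
    hysteresis_path,
    injury_pattern,
    p_alt,
    subject_summary,
)


@pytest.mark.parametrize("value, uln, expected", [
    (120, 40, 3.0), (40, 40, 1.0), (0, 40, 0.0)])
def test_fold_uln(value, uln, expected):
    assert fold_uln(value, uln) == expected


def test_fold_uln_domain_errors():
    with pytest.raises(ValueError):
        fold_uln(10, 0)
    with pytest.raises(ValueError):
        fold_uln(-1, 40)


@pytest.mark.parametrize("value, baseline, expected", [
    (90, 30, 3.0), (30, 30, 1.0)])
def test_fold_baseline(value, baseline, expected):
    assert fold_baseline(value, baseline) == expected


def test_fold_baseline_absent_when_zero_or_missing():
    assert math.isnan(fold_baseline(90, 0))
    assert math.isnan(fold_baseline(90, None))


def test_visit_ratios_from_same_day_folds():
    study = make_study([
        ("S01", "ALT", 120, 40, 8),   # fold 3.0
        ("S01", "AST", 160, 40, 8),   # fold 4.0
        ("S01", "ALP", 150, 120, 8),  # fold 1.25
        ("S01", "TB", 1.2, 1.2, 8),
        ("S01", "ALT", 80, 40, 15),   # no same-day ALP
        ("S01", "TB", 1.0, 1.2, 15),
    ])
    visits = compute_visit_derived(study).set_index("study_day")
    assert visits.loc[8, "r_ratio"] == pytest.approx(3.0 / 1.25)  # 2.4
    assert visits.loc[8, "nr_ratio"] == pytest.approx(4.0 / 1.25)  # 3.2
    assert math.isnan(visits.loc[15, "r_ratio"])
    assert math.isnan(visits.loc[15, "nr_ratio"])


def test_nr_equals_r_when_ast_below_alt():
    study = make_study([
        ("S01", "ALT", 200, 40, 8), ("S01", "AST", 100, 40, 8),
        ("S01", "ALP", 150, 120, 8), ("S01", "TB", 1.0, 1.2, 8)])
    visits = compute_visit_derived(study)
    assert visits.iloc[0]["nr_ratio"] == visits.iloc[0]["r_ratio"]


def test_p_alt_contract():
    c = PAltConstants()
    assert p_alt(30, 30, c) == 0.0
    assert p_alt(20, 30, c) == 0.0
    assert p_alt(1e9, 20, c) == 100.0
    # hand-computed: 100 * (500-20) * 3 / 30000
    assert p_alt(500, 20, c) == pytest.approx(4.8)
    with pytest.raises(ValueError):
        p_alt(-1, 0, c)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(peaks=st.lists(st.floats(0, 5000), min_size=2, max_size=2),
       baseline=st.floats(0, 500))
def test_p_alt_nondecreasing_in_peak(peaks, baseline):
    lo, hi = sorted(peaks)
    assert p_alt(lo, baseline) <= p_alt(hi, baseline)


@pytest.mark.parametrize("ratio, expected", [
    (5.0, "hepatocellular"), (7.5, "hepatocellular"),
    (2.0, "cholestatic"), (0.5, "cholestatic"),
    (3.7, "mixed"), (2.001, "mixed"), (4.999, "mixed"),
    (float("nan"), "indeterminate")])
def test_injury_pattern_boundaries(ratio, expected):
    assert injury_pattern(ratio) == expected


def test_injury_pattern_exclusive_boundaries_configurable():
    cfg = EdishConfig(boundary_inclusive=False)
    assert injury_pattern(5.0, cfg) == "mixed"
    assert injury_pattern(2.0, cfg) == "mixed"


def test_injury_pattern_is_step_function_with_two_breakpoints():
    grid = np.linspace(0.1, 8, 400)
    labels = [injury_pattern(r) for r in grid]
    changes = [(grid[i], labels[i], labels[i + 1])
               for i in range(len(grid) - 1) if labels[i] != labels[i + 1]]
    assert len(changes) == 2
    assert changes[0][1:] == ("cholestatic", "mixed")
    assert changes[1][1:] == ("mixed", "hepatocellular")


def test_peak_tie_breaks_to_earliest_day():
    study = make_study([
        ("S01", "ALT", 30, 40, -3), ("S01", "ALT", 120, 40, 8),
        ("S01", "ALT", 120, 40, 15), ("S01", "TB", 1.0, 1.2, 8)])
    row = subject_summary(study).iloc[0]
    assert row["ALT_baseline"] == 30.0
    assert row["ALT_peak_fold"] == 3.0
    assert row["ALT_peak_day"] == 8


def test_peak_time_separation_and_window():
    study = make_study([
        ("S01", "ALT", 120, 40, 8), ("S01", "ALT", 90, 40, 22),
        ("S01", "TB", 1.0, 1.2, 8), ("S01", "TB", 3.0, 1.2, 22)])
    row = subject_summary(study).iloc[0]
    assert row["peak_time_separation_days"] == 14
    assert bool(row["within_window"]) is True
    row30 = subject_summary(study, EdishConfig(peak_window_days=10)).iloc[0]
    assert bool(row30["within_window"]) is False


def test_non_evaluable_subject_retained_not_dropped():
    study = make_study([
        ("S01", "ALT", 120, 40, 8), ("S01", "TB", 1.0, 1.2, 8),
        ("S02", "ALT", 120, 40, 8)])  # S02 has no TB at all
    summ = subject_summary(study)
    assert set(summ["subject_id"]) == {"S01", "S02"}
    s02 = summ[summ["subject_id"] == "S02"].iloc[0]
    assert not s02["evaluable"]
    assert pd.isna(s02["peak_time_separation_days"])


def test_summary_matches_brute_force_oracle(small_noisy_study):
    study, _ = small_noisy_study
    summaries = subject_summary(study)
    assert_matches_oracle(summaries, brute_force_summary(study))


def test_scale_invariance_of_folds_ratios_and_labels(small_noisy_study):
    study, _ = small_noisy_study
    scaled = copy.deepcopy(study)
    scaled.records["value"] *= 7.3
    scaled.records["uln"] *= 7.3
    v1, v2 = compute_visit_derived(study), compute_visit_derived(scaled)
    for col in v1.columns.drop(["subject_id", "study_day"]):
        assert np.array_equal(v1[col].to_numpy(), v2[col].to_numpy(), equal_nan=True)
    s1, s2 = subject_summary(study), subject_summary(scaled)
    for col in ("ALT_peak_fold", "TB_peak_fold", "ALT_peak_day", "TB_peak_day",
                "pattern_ratio", "injury_pattern", "peak_time_separation_days"):
        assert s1[col].equals(s2[col])


def test_hysteresis_path_co_measured():
    study = make_study([
        ("S01", "ALT", 40, 40, 1), ("S01", "ALT", 120, 40, 8),
        ("S01", "TB", 1.2, 1.2, 1), ("S01", "TB", 2.4, 1.2, 8)])
    path = hysteresis_path(study, "S01")
    assert list(path["study_day"]) == [1, 8]
    assert list(path["ALT_fold"]) == [1.0, 3.0]
    assert list(path["TB_fold"]) == [1.0, 2.0]


def test_hysteresis_locf_fills_missing_analyte():
    study = make_study([
        ("S01", "ALT", 40, 40, 1), ("S01", "ALT", 120, 40, 8),
        ("S01", "TB", 1.2, 1.2, 1)])
    path = hysteresis_path(study, "S01")
    assert list(path["study_day"]) == [1, 8]
    assert path.iloc[1]["TB_fold"] == 1.0  # carried forward from day 1
    dropped = hysteresis_path(study, "S01", EdishConfig(locf_hysteresis=False))
    assert list(dropped["study_day"]) == [1]


def test_hysteresis_starts_when_both_observed():
    study = make_study([
        ("S01", "ALT", 40, 40, 1), ("S01", "TB", 1.2, 1.2, 8),
        ("S01", "ALT", 120, 40, 8), ("S01", "TB", 2.4, 1.2, 15)])
    path = hysteresis_path(study, "S01")
    assert list(path["study_day"]) == [8, 15]  # day 1 lacks TB, LOCF has nothing yet


def test_hysteresis_matches_merge_oracle(small_noisy_study):
    study, _ = small_noisy_study
    sid = study.subjects()[0]
    path = hysteresis_path(study, sid)
    # independent merge-and-fill over raw records
    rec = study.records
    mine = rec[rec["subject_id"] == sid]
    series = {}
    for analyte in ("ALT", "TB"):
        sub = mine[mine["analyte"] == analyte]
        series[analyte] = {int(d): float(format(v / u, ".9g")) for d, v, u in
                           zip(sub["study_day"], sub["value"], sub["uln"])}
    days = sorted(set(series["ALT"]) | set(series["TB"]))
    expected, last = [], {}
    for d in days:
        for a in ("ALT", "TB"):
            if d in series[a]:
                last[a] = series[a][d]
        if "ALT" in last and "TB" in last:
            expected.append((d, last["ALT"], last["TB"]))
    assert [(int(d), a, t) for d, a, t in
            zip(path["study_day"], path["ALT_fold"], path["TB_fold"])] == expected


def test_subject_not_found():
    from edish.config import SubjectNotFoundError
    study = make_study([("S01", "ALT", 120, 40, 8), ("S01", "TB", 1.0, 1.2, 8)])
    with pytest.raises(SubjectNotFoundError):
        hysteresis_path(study, "NOPE")
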