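"""Shared fixtures and the independent brute-force reference implementation.

The oracle below recomputes per-subject summaries by plain Python scans over
raw records — no pandas group operations, no code shared with the derive
module — so agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest

from edish.config import EdishConfig, PAltConstants
from edish.ingest import RECORD_COLUMNS, Study
from edish.synthetic import SimSpec, simulate_study

ACCEPTANCE_MIX = {"hys_law": 3, "temples": 5, "hyperbili": 5,
                  "cholestatic": 10, "mixed": 10, "normal": 167}


def make_study(rows, attributes=None):
    """Build a Study straight from (subject, analyte, value, uln, day) tuples."""
    rec = pd.DataFrame(rows, columns=["subject_id", "analyte", "value", "uln", "study_day"])
    rec["baseline_flag"] = False
    rec = (rec.sort_values(["subject_id", "analyte", "study_day"])
           .reset_index(drop=True)[list(RECORD_COLUMNS)])
    attrs = None
    if attributes is not None:
        attrs = pd.DataFrame.from_dict(attributes, orient="index")
        attrs.index.name = "subject_id"
    return Study(records=rec, subject_attributes=attrs)


@pytest.fixture(scope="session")
def zero_noise_study():
    """200 subjects, designed phenotype mix, no measurement noise."""
    spec = SimSpec(n_subjects=200, mix=dict(ACCEPTANCE_MIX), noise_sd=0.0, seed=42)
    return simulate_study(spec)


@pytest.fixture(scope="session")
def small_noisy_study():
    spec = SimSpec(n_subjects=50, seed=11)
    return simulate_study(spec)


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_round9(x: float) -> float:
    """Independent 9-significant-digit rounding via decimal formatting."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    return float(format(x, ".9g"))


def brute_force_summary(study: Study,
                        cfg: EdishConfig = EdishConfig(),
                        constants: PAltConstants = PAltConstants()) -> dict:
    """Full-scan reference: subject -> summary dict.

    Enumerates every record per subject; peaks over day > 1 with earliest-day
    ties; baseline = value at the latest day <= 1 (flag overrides); pattern
    via the visit-basis R at the ALT peak day.
    """
    by_subject: dict[str, list] = {}
    for row in study.records.itertuples(index=False):
        by_subject.setdefault(row.subject_id, []).append(row)

    out = {}
    for sid, rows in by_subject.items():
        summary: dict = {"subject_id": sid}
        peaks: dict = {}
        for analyte in ("ALT", "AST", "ALP", "TB"):
            mine = [r for r in rows if r.analyte == analyte]
            # baseline: explicit flag wins, else latest day <= 1
            flagged = [r for r in mine if r.baseline_flag]
            pre = flagged or [r for r in mine if r.study_day <= 1]
            baseline = None
            if pre:
                best_day = max(r.study_day for r in pre)
                baseline = [r for r in pre if r.study_day == best_day][0].value
            summary[f"{analyte}_baseline"] = baseline
            best = None
            for r in sorted(mine, key=lambda r: r.study_day):
                if r.study_day <= 1:
                    continue
                fold = oracle_round9(r.value / r.uln)
                if best is None or fold > best[0]:
                    best = (fold, r.study_day, r.value)
            peaks[analyte] = best
            summary[f"{analyte}_peak_fold"] = None if best is None else best[0]
            summary[f"{analyte}_peak_day"] = None if best is None else best[1]
            summary[f"{analyte}_peak_value"] = None if best is None else best[2]
        evaluable = peaks["ALT"] is not None and peaks["TB"] is not None
        summary["evaluable"] = evaluable
        if evaluable:
            sep = abs(peaks["ALT"][1] - peaks["TB"][1])
            summary["peak_time_separation_days"] = sep
            summary["within_window"] = sep <= cfg.peak_window_days
            base_alt = summary["ALT_baseline"] or 0.0
            rise = peaks["ALT"][2] - base_alt
            pct = 0.0 if rise <= 0 else min(
                100.0 * rise * constants.distribution_volume_l
                / constants.hepatic_alt_capacity, 100.0)
            summary["p_alt_percent"] = oracle_round9(pct)
            # visit-basis R at the ALT peak day
            day = peaks["ALT"][1]
            alt_rec = [r for r in rows if r.analyte == "ALT" and r.study_day == day]
            alp_rec = [r for r in rows if r.analyte == "ALP" and r.study_day == day]
            if alt_rec and alp_rec and alp_rec[0].value > 0:
                alt_fold = oracle_round9(alt_rec[0].value / alt_rec[0].uln)
                alp_fold = oracle_round9(alp_rec[0].value / alp_rec[0].uln)
                ratio = oracle_round9(alt_fold / alp_fold)
                if ratio >= cfg.hepatocellular_cut:
                    summary["injury_pattern"] = "hepatocellular"
                elif ratio <= cfg.cholestatic_cut:
                    summary["injury_pattern"] = "cholestatic"
                else:
                    summary["injury_pattern"] = "mixed"
            else:
                summary["injury_pattern"] = "indeterminate"
        out[sid] = summary
    return out


def assert_matches_oracle(summaries: pd.DataFrame, oracle: dict) -> None:
    """Exact field-by-field comparison of subject_summary against the oracle."""
    assert set(summaries["subject_id"]) == set(oracle)
    for _, row in summaries.iterrows():
        ref = oracle[row["subject_id"]]
        assert bool(row["evaluable"]) == ref["evaluable"], row["subject_id"]
        for analyte in ("ALT", "AST", "ALP", "TB"):
            for part in ("baseline", "peak_fold", "peak_day", "peak_value"):
                got = row[f"{analyte}_{part}"]
                want = ref[f"{analyte}_{part}"]
                if want is None:
                    assert pd.isna(got), (row["subject_id"], analyte, part)
                else:
                    assert got == want, (row["subject_id"], analyte, part, got, want)
        if ref["evaluable"]:
            assert int(row["peak_time_separation_days"]) == ref["peak_time_separation_days"]
            assert bool(row["within_window"]) == ref["within_window"]
            assert row["p_alt_percent"] == ref["p_alt_percent"]
            assert row["injury_pattern"] == ref["injury_pattern"]
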