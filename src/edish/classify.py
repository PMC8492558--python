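"""eDISH quadrant classification, grouped counts and the triage table.

The eDISH plane is split at the configured ALT (x) and bilirubin (y) fold
thresholds into the four clinical-concern regions: possible Hy's Law (both
elevated), Temple's Corollary (ALT only), hyperbilirubinemia (bilirubin
only), and within range.  Thresholds are inclusive on the flagged side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, DataValidationError, EdishConfig

#: quadrants in decreasing clinical severity (triage order)
QUADRANTS = ("possible_hys_law", "temples_corollary", "hyperbilirubinemia", "within_range")


def classify_quadrant(x: float, y: float, cfg: EdishConfig = EdishConfig()) -> str:
    """Quadrant of a single (x, y) = (peak ALT-axis value, peak TB fold) point.

    Thresholds are inclusive on the flagged side: a point exactly at a
    threshold is flagged.
    """
    if x is None or y is None or np.isnan(x) or np.isnan(y):
        raise DataValidationError("not classifiable: missing peak value")
    x_hot = x >= cfg.x_threshold
    y_hot = y >= cfg.tb_fold_threshold
    if x_hot and y_hot:
        return "possible_hys_law"
    if x_hot:
        return "temples_corollary"
    if y_hot:
        return "hyperbilirubinemia"
    return "within_range"


def _axis_values(summary_row: pd.Series, cfg: EdishConfig) -> tuple[float, float]:
    """(x, y) for one subject under the configured axis mode."""
    if cfg.x_axis_mode == "fold_baseline":
        return (summary_row["ALT_peak_fold_baseline"],
                summary_row["TB_peak_fold_baseline"])
    if cfg.x_axis_mode == "nr":
        return summary_row["nr_subject"], summary_row["TB_peak_fold"]
    return summary_row["ALT_peak_fold"], summary_row["TB_peak_fold"]


def assign_quadrants(summaries: pd.DataFrame,
                     cfg: EdishConfig = EdishConfig()) -> pd.DataFrame:
    """Add ``x``, ``y`` and ``quadrant`` columns to a subject-summary table.

    Non-evaluable subjects get a null quadrant (they are not classifiable).
    """
    out = summaries.copy()
    xs, ys, quads = [], [], []
    for _, row in out.iterrows():
        if not row["evaluable"]:
            xs.append(np.nan), ys.append(np.nan), quads.append(None)
            continue
        x, y = _axis_values(row, cfg)
        xs.append(x), ys.append(y)
        if x is None or y is None or np.isnan(x) or np.isnan(y):
            quads.append(None)
        else:
            quads.append(classify_quadrant(x, y, cfg))
    out["x"], out["y"], out["quadrant"] = xs, ys, quads
    return out


def quadrant_counts(summaries: pd.DataFrame,
                    cfg: EdishConfig = EdishConfig(),
                    group_by: str | None = None,
                    attributes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Quadrant x group count table over classifiable subjects.

    Without grouping, one ``count`` column.  Counts always sum to the number
    of classifiable subjects; empty groups report 0.
    """
    labelled = summaries if "quadrant" in summaries.columns else assign_quadrants(summaries, cfg)
    labelled = labelled[labelled["quadrant"].notna()]
    if group_by is None:
        counts = labelled["quadrant"].value_counts()
        return pd.DataFrame({"count": [int(counts.get(q, 0)) for q in QUADRANTS]},
                            index=pd.Index(QUADRANTS, name="quadrant"))
    if attributes is None or group_by not in attributes.columns:
        raise ConfigurationError(f"unknown grouping column {group_by!r}")
    merged = labelled.merge(attributes[[group_by]], left_on="subject_id",
                            right_index=True, how="left")
    groups = sorted(attributes[group_by].dropna().unique().astype(str))
    table = pd.DataFrame(0, index=pd.Index(QUADRANTS, name="quadrant"),
                         columns=groups, dtype=int)
    for (quad, grp), n in merged.groupby(["quadrant", group_by]).size().items():
        table.loc[quad, str(grp)] = int(n)
    return table


TRIAGE_COLUMNS = ("subject_id", "quadrant", "ALT_peak_fold", "ALT_peak_day",
                  "TB_peak_fold", "TB_peak_day", "peak_time_separation_days",
                  "within_window", "injury_pattern", "p_alt_percent")


def triage_table(summaries: pd.DataFrame,
                 cfg: EdishConfig = EdishConfig()) -> pd.DataFrame:
    """Per-subject listing ordered for review triage.

    Possible Hy's Law cases first, then Temple's Corollary,
    hyperbilirubinemia and within-range; within a quadrant by peak ALT fold
    descending, ties by subject id.  Non-evaluable subjects are excluded
    (they appear in the validation report instead).
    """
    labelled = summaries if "quadrant" in summaries.columns else assign_quadrants(summaries, cfg)
    labelled = labelled[labelled["quadrant"].notna()].copy()
    severity = {q: i for i, q in enumerate(QUADRANTS)}
    labelled["_sev"] = labelled["quadrant"].map(severity)
    labelled = labelled.sort_values(
        ["_sev", "ALT_peak_fold", "subject_id"],
        ascending=[True, False, True]).drop(columns="_sev")
    return labelled[list(TRIAGE_COLUMNS)].reset_index(drop=True)
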