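"""Per-visit and per-subject hepatotoxicity statistics.

Implements fold-ULN and fold-baseline normalization, the R and nR
liver-injury-pattern ratios, treatment-emergent peak detection, peak-time
separation, the P_ALT hepatocyte-loss estimate, injury-pattern labelling and
the ALT-vs-bilirubin hysteresis path.

Numerical contract
------------------
All derived folds and ratios are defined at :data:`SIG_DIGITS` significant
digits.  Laboratory assays carry 2-3 significant digits at best, so nothing
scientific is lost, and at this precision the derived quantities are exactly
invariant under a common rescaling of values and ULNs (unit changes), which
raw floating-point division is not.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ANALYTES, EdishConfig, PAltConstants, SubjectNotFoundError
from .ingest import Study, evaluability

#: significant digits at which derived folds/ratios are defined
SIG_DIGITS = 9

INJURY_PATTERNS = ("hepatocellular", "cholestatic", "mixed", "indeterminate")


def sig_round(x, digits: int = SIG_DIGITS):
    """Round to ``digits`` significant digits (vectorized, NaN-safe)."""
    x = np.asarray(x, dtype=float)
    out = np.array(x, dtype=float)
    mask = np.isfinite(x) & (x != 0)
    if mask.any():
        mags = np.floor(np.log10(np.abs(x[mask])))
        decimals = digits - 1 - mags
        # np.round takes a scalar decimals; group by exponent
        rounded = np.empty(mask.sum())
        vals = x[mask]
        for d in np.unique(decimals):
            sel = decimals == d
            rounded[sel] = np.round(vals[sel], int(d))
        out[mask] = rounded
    if np.ndim(x) == 0:
        return float(out)
    return out


def fold_uln(value: float, uln: float) -> float:
    """Fold change from the upper limit of normal, ``value / uln``."""
    if np.any(np.asarray(uln) <= 0):
        raise ValueError("uln must be > 0")
    if np.any(np.asarray(value) < 0):
        raise ValueError("value must be >= 0")
    return sig_round(np.asarray(value, dtype=float) / np.asarray(uln, dtype=float))


def fold_baseline(value: float, baseline: float | None) -> float:
    """Fold change from baseline, or NaN when baseline is missing or zero."""
    value = np.asarray(value, dtype=float)
    if baseline is None:
        return float("nan") if value.ndim == 0 else np.full(value.shape, np.nan)
    baseline = np.asarray(baseline, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((baseline > 0) & np.isfinite(baseline),
                       value / np.where(baseline > 0, baseline, np.nan), np.nan)
    return sig_round(out)


def p_alt(peak_alt: float, baseline_alt: float,
          constants: PAltConstants = PAltConstants()) -> float:
    """Estimated percent hepatocyte loss from the serum-ALT rise.

    Released-ALT mass balance: the ALT rise over baseline times the
    distribution volume, as a fraction of whole-liver ALT capacity, clipped
    to [0, 100].  Zero when the peak does not exceed baseline.
    """
    if peak_alt < 0 or baseline_alt < 0:
        raise ValueError("ALT values must be >= 0")
    rise = peak_alt - baseline_alt
    if rise <= 0:
        return 0.0
    pct = 100.0 * rise * constants.distribution_volume_l / constants.hepatic_alt_capacity
    return sig_round(min(pct, 100.0))


def injury_pattern(ratio: float, cfg: EdishConfig = EdishConfig()) -> str:
    """Classify an R/nR ratio as hepatocellular, cholestatic or mixed.

    CIOMS convention: ratio >= 5 hepatocellular, <= 2 cholestatic, strictly
    between mixed; an absent (NaN) ratio is indeterminate.  Boundary
    inclusion is configurable via ``cfg.boundary_inclusive``.
    """
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "indeterminate"
    hi, lo = cfg.hepatocellular_cut, cfg.cholestatic_cut
    if cfg.boundary_inclusive:
        if ratio >= hi:
            return "hepatocellular"
        if ratio <= lo:
            return "cholestatic"
    else:
        if ratio > hi:
            return "hepatocellular"
        if ratio < lo:
            return "cholestatic"
        if ratio in (lo, hi):
            return "mixed"
    return "mixed"


def baseline_table(study: Study) -> pd.DataFrame:
    """Per (subject, analyte) baseline values.

    An explicit baseline flag from the mapping wins; otherwise the record at
    the latest study day <= 1 (CDISC convention: day <= 1 is pre/at first
    dose).  Index (subject_id, analyte), column ``baseline``.
    """
    rec = study.records
    flagged = rec[rec["baseline_flag"]]
    base_flag = (flagged.sort_values("study_day")
                 .groupby(["subject_id", "analyte"])["value"].last())
    pre = rec[rec["study_day"] <= 1]
    base_day = (pre.sort_values("study_day")
                .groupby(["subject_id", "analyte"])["value"].last())
    base = base_day.copy()
    base.loc[base_flag.index] = base_flag
    return base.rename("baseline").to_frame()


def _pivot(study: Study, column: str) -> pd.DataFrame:
    """(subject, day) x analyte table of one record column."""
    return study.records.pivot_table(
        index=["subject_id", "study_day"], columns="analyte",
        values=column, aggfunc="first")


def compute_visit_derived(study: Study, cfg: EdishConfig = EdishConfig()) -> pd.DataFrame:
    """Per-(subject, day) derived values: folds, fold-baselines, R and nR.

    R = (ALT fold-ULN)/(ALP fold-ULN) and
    nR = max(ALT, AST fold-ULN)/(ALP fold-ULN), each defined only at visits
    with a same-day positive ALP fold (and the respective numerator present).
    """
    values = _pivot(study, "value")
    ulns = _pivot(study, "uln")
    out = pd.DataFrame(index=values.index)
    base = baseline_table(study)["baseline"]
    for analyte in ANALYTES:
        if analyte in values.columns:
            v = values[analyte].to_numpy()
            u = ulns[analyte].to_numpy()
            with np.errstate(invalid="ignore"):
                out[f"{analyte}_fold"] = sig_round(v / u)
            b = values.index.get_level_values("subject_id").map(
                lambda s, a=analyte: base.get((s, a), np.nan)).to_numpy(dtype=float)
            out[f"{analyte}_fold_baseline"] = fold_baseline(v, b)
        else:
            out[f"{analyte}_fold"] = np.nan
            out[f"{analyte}_fold_baseline"] = np.nan
    alt, ast, alp = (out["ALT_fold"].to_numpy(), out["AST_fold"].to_numpy(),
                     out["ALP_fold"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(alp > 0, alp, np.nan)
        out["r_ratio"] = sig_round(alt / denom)
        numer = np.fmax(alt, ast)  # fmax ignores NaN on one side
        out["nr_ratio"] = sig_round(numer / denom)
    return out.reset_index()


def _peak(frame: pd.DataFrame, fold_col: str) -> pd.Series | None:
    """Earliest row attaining the maximum of ``fold_col`` (NaN-free rows only)."""
    ok = frame.dropna(subset=[fold_col])
    if ok.empty:
        return None
    best = ok[fold_col].max()
    return ok[ok[fold_col] == best].sort_values("study_day").iloc[0]


def subject_summary(
    study: Study,
    cfg: EdishConfig = EdishConfig(),
    constants: PAltConstants = PAltConstants(),
) -> pd.DataFrame:
    """One row per subject: baselines, treatment-emergent peaks, separation,
    P_ALT, injury pattern and the subject-level R/nR ratios.

    Peaks are taken over post-baseline visits only (study day > 1), ties
    broken to the earliest day.  Non-evaluable subjects (no post-baseline ALT
    or TB) are retained with ``evaluable = False``, never silently dropped.
    """
    visits = compute_visit_derived(study, cfg)
    values = _pivot(study, "value").reset_index()
    visits = visits.merge(values, on=["subject_id", "study_day"],
                          suffixes=("", "_value"))
    # analyte columns from the value pivot keep their bare names; disambiguate
    val_cols = {a: (a if a in visits.columns else None) for a in ANALYTES}
    base = baseline_table(study)["baseline"]
    evaluable_ids, non_eval = evaluability(study.records)

    rows = []
    for sid, gall in visits.groupby("subject_id", sort=True):
        g = gall[gall["study_day"] > 1]
        row: dict = {"subject_id": sid}
        for analyte in ANALYTES:
            b = base.get((sid, analyte), np.nan)
            row[f"{analyte}_baseline"] = b
            pk = _peak(g, f"{analyte}_fold")
            if pk is None:
                row[f"{analyte}_peak_value"] = np.nan
                row[f"{analyte}_peak_fold"] = np.nan
                row[f"{analyte}_peak_day"] = np.nan
            else:
                col = val_cols[analyte]
                row[f"{analyte}_peak_value"] = pk[col] if col else np.nan
                row[f"{analyte}_peak_fold"] = pk[f"{analyte}_fold"]
                row[f"{analyte}_peak_day"] = int(pk["study_day"])
            pkb = _peak(g, f"{analyte}_fold_baseline")
            row[f"{analyte}_peak_fold_baseline"] = (
                np.nan if pkb is None else pkb[f"{analyte}_fold_baseline"])
        evaluable = sid in evaluable_ids
        row["evaluable"] = evaluable
        if evaluable:
            sep = abs(int(row["ALT_peak_day"]) - int(row["TB_peak_day"]))
            row["peak_time_separation_days"] = sep
            row["within_window"] = sep <= cfg.peak_window_days
            pa_base = row["ALT_baseline"]
            row["p_alt_percent"] = p_alt(
                row["ALT_peak_value"],
                0.0 if (pa_base is None or np.isnan(pa_base)) else pa_base,
                constants)
        else:
            row["peak_time_separation_days"] = np.nan
            row["within_window"] = False
            row["p_alt_percent"] = np.nan
        # subject-level pattern ratio
        numer_fold = ("ALT_fold" if cfg.pattern_basis == "r" else None)
        if cfg.ratio_basis == "peak":
            if cfg.pattern_basis == "r":
                num = row["ALT_peak_fold"]
            else:
                num = np.nanmax([row["ALT_peak_fold"], row["AST_peak_fold"]])
            den = row["ALP_peak_fold"]
            ratio = sig_round(num / den) if (np.isfinite(num) and np.isfinite(den)
                                             and den > 0) else np.nan
        else:
            # visit basis: ratio at the day of the peak numerator fold
            if cfg.pattern_basis == "r":
                pk = _peak(g, "ALT_fold")
            else:
                gtmp = g.assign(_num=np.fmax(g["ALT_fold"], g["AST_fold"]))
                pk = _peak(gtmp, "_num")
            ratio_col = "r_ratio" if cfg.pattern_basis == "r" else "nr_ratio"
            ratio = np.nan if pk is None else pk[ratio_col]
        row["pattern_ratio"] = ratio
        row["injury_pattern"] = injury_pattern(
            float(ratio) if ratio is not None else float("nan"), cfg)
        # subject-level nR for the nR axis mode (same basis convention)
        if cfg.ratio_basis == "peak":
            num = np.nanmax([row["ALT_peak_fold"], row["AST_peak_fold"]])
            den = row["ALP_peak_fold"]
            row["nr_subject"] = (sig_round(num / den)
                                 if np.isfinite(num) and np.isfinite(den) and den > 0
                                 else np.nan)
        else:
            gtmp = g.assign(_num=np.fmax(g["ALT_fold"], g["AST_fold"]))
            pk = _peak(gtmp, "_num")
            row["nr_subject"] = np.nan if pk is None else pk["nr_ratio"]
        rows.append(row)

    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("subject_id").reset_index(drop=True)
    return out


def hysteresis_path(study: Study, subject_id: str,
                    cfg: EdishConfig = EdishConfig()) -> pd.DataFrame:
    """Ordered (study_day, ALT_fold, TB_fold) path for one subject.

    Days missing one analyte carry the last observation forward (LOCF) so the
    path stays defined at every observation day; with
    ``cfg.locf_hysteresis = False`` incomplete days are dropped instead.
    The path starts at the first day where both analytes have been observed.
    """
    rec = study.subject_records(subject_id)
    series = {}
    for analyte in ("ALT", "TB"):
        sub = rec[rec["analyte"] == analyte].sort_values("study_day")
        series[analyte] = pd.Series(
            sig_round(sub["value"].to_numpy() / sub["uln"].to_numpy()),
            index=sub["study_day"].to_numpy())
    days = sorted(set(series["ALT"].index) | set(series["TB"].index))
    frame = pd.DataFrame(index=pd.Index(days, name="study_day"),
                         data={"ALT_fold": series["ALT"].reindex(days),
                               "TB_fold": series["TB"].reindex(days)})
    if cfg.locf_hysteresis:
        frame = frame.ffill()
    frame = frame.dropna()
    return frame.reset_index()


def derived_tables(study: Study, cfg: EdishConfig = EdishConfig(),
                   constants: PAltConstants = PAltConstants()) -> dict[str, pd.DataFrame]:
    """Both derived tables keyed by name, for export as delimited text."""
    return {
        "visit_derived": compute_visit_derived(study, cfg),
        "subject_summary": subject_summary(study, cfg, constants),
    }
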