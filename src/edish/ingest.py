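"""Reading, dialect detection and normalization of laboratory tables.

Accepts delimited text in an SDTM LB-like dialect (USUBJID/LBTESTCD/LBSTRESN/
LBSTNRHI/LBDY), an ADaM ADLB-like dialect (USUBJID/PARAMCD/AVAL/ANRHI|A1HI/
ADY), or arbitrary columns plus a user-supplied mapping, and normalizes all
of them to one internal :class:`Study` model.  Unmappable rows are never
silently dropped: every exclusion is counted by reason and surfaced in the
validation report.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import (
    ANALYTES,
    DEFAULT_ANALYTE_SYNONYMS,
    ConfigurationError,
    DataValidationError,
    EdishConfig,
    logger,
)

SDTM_SIGNATURE = {"USUBJID", "LBTESTCD", "LBSTRESN", "LBSTNRHI", "LBDY"}
ADAM_CORE_SIGNATURE = {"USUBJID", "PARAMCD", "AVAL", "ADY"}
ADAM_RANGE_VARS = ("ANRHI", "A1HI")

#: canonical column order of Study.records
RECORD_COLUMNS = ("subject_id", "analyte", "value", "uln", "study_day", "baseline_flag")

REQUIRED_BINDINGS = ("subject_id", "analyte_code", "result_value", "uln_value", "study_day")


@dataclass(frozen=True)
class MappingConfig:
    """Column bindings plus the analyte-code dictionary for one raw table."""

    subject_id: str
    analyte_code: str
    result_value: str
    uln_value: str
    study_day: str
    baseline_flag: str | None = None
    group_columns: tuple[str, ...] = ()
    analyte_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_SYNONYMS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_columns", tuple(self.group_columns))
        amap = {str(k).strip().upper(): v for k, v in dict(self.analyte_map).items()}
        for code, canon in amap.items():
            if canon not in ANALYTES:
                raise ConfigurationError(
                    f"analyte_map maps {code!r} to non-canonical analyte {canon!r}")
        object.__setattr__(self, "analyte_map", amap)
        missing = sorted(set(ANALYTES) - set(amap.values()))
        if missing:
            # reported, not silently dropped: folds for these analytes will
            # simply be absent downstream
            logger.warning("analyte_map covers no source code for: %s", ", ".join(missing))


def mapping_from_file(path: str | Path) -> MappingConfig:
    """Load a YAML/JSON mapping config; keys are the MappingConfig field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"mapping file {path} must be a mapping")
    allowed = {"subject_id", "analyte_code", "result_value", "uln_value",
               "study_day", "baseline_flag", "group_columns", "analyte_map"}
    for key in raw:
        if key not in allowed:
            raise ConfigurationError(f"unknown mapping key {key!r}")
    for binding in REQUIRED_BINDINGS:
        if binding not in raw:
            raise ConfigurationError(f"required mapping binding {binding!r} missing")
    amap = raw.get("analyte_map")
    if amap is None:
        amap = dict(DEFAULT_ANALYTE_SYNONYMS)
    return MappingConfig(
        subject_id=raw["subject_id"],
        analyte_code=raw["analyte_code"],
        result_value=raw["result_value"],
        uln_value=raw["uln_value"],
        study_day=raw["study_day"],
        baseline_flag=raw.get("baseline_flag"),
        group_columns=tuple(raw.get("group_columns", ()) or ()),
        analyte_map=amap,
    )


@dataclass
class Study:
    """Validated, normalized collection of lab records.

    ``records`` has columns :data:`RECORD_COLUMNS` in canonical order
    (sorted by subject, analyte, day).  ``subject_attributes`` is an optional
    per-subject categorical table indexed by subject id.
    """

    records: pd.DataFrame
    subject_attributes: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    exclusions: Counter = field(default_factory=Counter)
    warnings: list[str] = field(default_factory=list)

    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    def subject_records(self, subject_id: str) -> pd.DataFrame:
        sub = self.records[self.records["subject_id"] == subject_id]
        if sub.empty:
            from .config import SubjectNotFoundError
            raise SubjectNotFoundError(subject_id)
        return sub


@dataclass
class ValidationReport:
    """Machine-readable accounting of one normalization pass."""

    n_subjects: int
    n_evaluable: int
    non_evaluable: dict[str, str]           # subject_id -> reason
    excluded_rows: dict[str, int]           # reason -> count
    n_records: int
    warnings: list[str]
    error: bool = False

    @property
    def n_non_evaluable(self) -> int:
        return len(self.non_evaluable)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_evaluable": self.n_evaluable,
            "n_non_evaluable": self.n_non_evaluable,
            "non_evaluable": dict(self.non_evaluable),
            "excluded_rows": dict(self.excluded_rows),
            "n_records": self.n_records,
            "warnings": list(self.warnings),
            "error": self.error,
        }

    def write(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    text_head = Path(path).open().readline()
    try:
        dialect = csv.Sniffer().sniff(text_head, delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])
    if df.empty:
        raise DataValidationError("empty input")
    return df


def detect_dialect(raw: pd.DataFrame) -> str:
    """Classify a raw table as ``sdtm``, ``adam`` or ``unknown`` by signature columns.

    If both signatures are present the tie resolves to ``adam``
    (analysis-ready data trumps tabulation data) and the tie is logged.
    """
    if raw.empty and raw.columns.empty:
        raise DataValidationError("empty input")
    cols = set(raw.columns)
    is_sdtm = SDTM_SIGNATURE <= cols
    is_adam = ADAM_CORE_SIGNATURE <= cols and any(v in cols for v in ADAM_RANGE_VARS)
    if is_sdtm and is_adam:
        logger.info("both SDTM and ADaM signatures present; preferring ADaM")
        return "adam"
    if is_adam:
        return "adam"
    if is_sdtm:
        return "sdtm"
    return "unknown"


def builtin_mapping(dialect: str, raw: pd.DataFrame, cfg: EdishConfig) -> MappingConfig:
    """Synthesize the mapping for a recognized CDISC-like dialect."""
    if dialect == "sdtm":
        return MappingConfig(
            subject_id="USUBJID", analyte_code="LBTESTCD", result_value="LBSTRESN",
            uln_value="LBSTNRHI", study_day="LBDY",
            baseline_flag="LBBLFL" if "LBBLFL" in raw.columns else None,
        )
    if dialect == "adam":
        preferred = cfg.adam_range_var
        range_var = preferred if preferred in raw.columns else next(
            (v for v in ADAM_RANGE_VARS if v in raw.columns), None)
        if range_var is None:
            raise ConfigurationError("required mapping binding 'uln_value' missing "
                                     "(no ANRHI or A1HI column)")
        return MappingConfig(
            subject_id="USUBJID", analyte_code="PARAMCD", result_value="AVAL",
            uln_value=range_var, study_day="ADY",
            baseline_flag="ABLFL" if "ABLFL" in raw.columns else None,
        )
    raise ConfigurationError(f"no built-in mapping for dialect {dialect!r}")


def _exact_numeric(series: pd.Series) -> pd.Series:
    """Coercing numeric parse via ``float()`` (correctly rounded, unlike the
    fast parser behind ``pd.to_numeric``), so text round-trips are exact."""
    def conv(s):
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan
    return series.map(conv).astype(float)


def _dedup(records: pd.DataFrame, policy: str) -> tuple[pd.DataFrame, int]:
    keys = ["subject_id", "analyte", "study_day"]
    n_before = len(records)
    if policy == "max":
        # conservative for safety screening: keep the worst (largest) value
        records = (records.sort_values(keys + ["value"])
                   .groupby(keys, as_index=False).last())
    elif policy == "first":
        records = records.groupby(keys, as_index=False).first()
    elif policy == "mean":
        agg = {"value": "mean", "uln": "first", "baseline_flag": "any"}
        records = records.groupby(keys, as_index=False).agg(agg)
    else:  # pragma: no cover - guarded by EdishConfig
        raise ConfigurationError(f"unknown dedup policy {policy!r}")
    return records, n_before - len(records)


def evaluability(records: pd.DataFrame) -> tuple[list[str], dict[str, str]]:
    """Split subjects into evaluable ids and non-evaluable ids with reasons.

    Evaluable means at least one post-baseline (day > 1) ALT record and one
    post-baseline TB record.
    """
    evaluable: list[str] = []
    reasons: dict[str, str] = {}
    post = records[records["study_day"] > 1]
    has_alt = set(post.loc[post["analyte"] == "ALT", "subject_id"])
    has_tb = set(post.loc[post["analyte"] == "TB", "subject_id"])
    for sid in sorted(records["subject_id"].unique()):
        missing = [name for name, ok in
                   (("ALT", sid in has_alt), ("TB", sid in has_tb)) if not ok]
        if missing:
            reasons[sid] = "no post-baseline " + " or ".join(missing)
        else:
            evaluable.append(sid)
    return evaluable, reasons


def normalize(
    raw: pd.DataFrame,
    mapping: MappingConfig | None = None,
    cfg: EdishConfig | None = None,
    subject_table: pd.DataFrame | None = None,
) -> Study:
    """Normalize a raw table to a :class:`Study`.

    With ``mapping=None`` the dialect is auto-detected and a built-in mapping
    synthesized; an ``unknown`` dialect then raises a configuration error.
    Rows that cannot yield a valid record are excluded and counted by reason.
    """
    cfg = cfg or EdishConfig()
    if raw.empty:
        raise DataValidationError("empty input")
    dialect = detect_dialect(raw)
    if mapping is None:
        if dialect == "unknown":
            raise ConfigurationError(
                "table matches no known dialect; supply a mapping config")
        mapping = builtin_mapping(dialect, raw, cfg)

    for binding in REQUIRED_BINDINGS:
        col = getattr(mapping, {"subject_id": "subject_id", "analyte_code": "analyte_code",
                                "result_value": "result_value", "uln_value": "uln_value",
                                "study_day": "study_day"}[binding])
        if col not in raw.columns:
            raise ConfigurationError(
                f"required mapping binding {binding!r} refers to missing column {col!r}")

    exclusions: Counter = Counter()
    warnings: list[str] = []
    n_input = len(raw)

    df = pd.DataFrame({
        "subject_id": raw[mapping.subject_id].astype(str),
        "code": raw[mapping.analyte_code].astype(str).str.strip().str.upper(),
        "value": _exact_numeric(raw[mapping.result_value]),
        "uln": _exact_numeric(raw[mapping.uln_value]),
        "study_day": _exact_numeric(raw[mapping.study_day]),
    })
    if mapping.baseline_flag and mapping.baseline_flag in raw.columns:
        df["baseline_flag"] = (raw[mapping.baseline_flag].astype(str)
                               .str.strip().str.upper().isin(("Y", "YES", "TRUE", "1")))
    else:
        df["baseline_flag"] = False

    df["analyte"] = df["code"].map(mapping.analyte_map)

    masks = {
        "unmapped_analyte": df["analyte"].isna(),
        "non_numeric_result": df["analyte"].notna() & df["value"].isna(),
    }
    keep = ~(masks["unmapped_analyte"] | masks["non_numeric_result"])

    # missing/invalid ULN: fall back to a configured study-level ULN per
    # analyte, else the record is excluded (fold-ULN undefined without it)
    bad_uln = keep & (df["uln"].isna() | (df["uln"] <= 0))
    if cfg.study_uln:
        fallback = df["analyte"].map(cfg.study_uln)
        fill = bad_uln & fallback.notna()
        df.loc[fill, "uln"] = fallback[fill]
        bad_uln &= ~fill
    masks["missing_uln"] = bad_uln
    keep &= ~bad_uln

    day_int = df["study_day"].round()
    bad_day = keep & (df["study_day"].isna() | (day_int == 0)
                      | (df["study_day"] != day_int))
    masks["invalid_study_day"] = bad_day
    keep &= ~bad_day

    bad_value = keep & (df["value"] < 0)
    masks["negative_result"] = bad_value
    keep &= ~bad_value

    for reason, mask in masks.items():
        n = int(mask.sum())
        if n:
            exclusions[reason] += n
            logger.warning("excluded %d row(s): %s", n, reason)
            warnings.append(f"excluded {n} row(s): {reason}")

    records = df.loc[keep, ["subject_id", "analyte", "value", "uln",
                            "study_day", "baseline_flag"]].copy()
    records["study_day"] = records["study_day"].astype(np.int64)
    records["value"] = records["value"].astype(float)
    records["uln"] = records["uln"].astype(float)

    records, n_dup = _dedup(records, cfg.dedup_policy)
    if n_dup:
        exclusions["duplicate_collapsed"] += n_dup
        warnings.append(f"collapsed {n_dup} duplicate (subject, analyte, day) row(s) "
                        f"with policy {cfg.dedup_policy!r}")

    if records.empty:
        raise DataValidationError("zero evaluable subjects after normalization")

    # heuristic mixed-units warning: ULN varying > 2x within an analyte
    for analyte, grp in records.groupby("analyte"):
        ulns = grp["uln"]
        if len(ulns) and ulns.max() > 2 * ulns.min():
            msg = (f"ULN for {analyte} varies more than 2x "
                   f"({ulns.min():g} to {ulns.max():g}); check for mixed units")
            logger.warning(msg)
            warnings.append(msg)

    records = (records.sort_values(["subject_id", "analyte", "study_day"])
               .reset_index(drop=True)[list(RECORD_COLUMNS)])

    attrs = None
    group_cols = [c for c in mapping.group_columns if c in raw.columns]
    if group_cols:
        attrs = (pd.DataFrame({"subject_id": raw[mapping.subject_id].astype(str)})
                 .join(raw[group_cols])
                 .drop_duplicates("subject_id")
                 .set_index("subject_id").sort_index())
    if subject_table is not None:
        st = subject_table.copy()
        id_col = "USUBJID" if "USUBJID" in st.columns else st.columns[0]
        st[id_col] = st[id_col].astype(str)
        st = st.drop_duplicates(id_col).set_index(id_col).sort_index()
        st.index.name = "subject_id"
        attrs = st if attrs is None else attrs.join(st, how="outer")

    evaluable, non_eval = evaluability(records)
    if not evaluable:
        raise DataValidationError("zero evaluable subjects after normalization")

    study = Study(
        records=records,
        subject_attributes=attrs,
        provenance={"dialect": dialect, "mapping": {
            "subject_id": mapping.subject_id, "analyte_code": mapping.analyte_code,
            "result_value": mapping.result_value, "uln_value": mapping.uln_value,
            "study_day": mapping.study_day, "baseline_flag": mapping.baseline_flag},
            "n_input_rows": n_input},
        exclusions=exclusions,
        warnings=warnings,
    )
    return study


def validate(study: Study) -> ValidationReport:
    """Pure accounting pass over a normalized study."""
    records = study.records
    subjects = study.subjects()
    evaluable, non_eval = evaluability(records)
    report = ValidationReport(
        n_subjects=len(subjects),
        n_evaluable=len(evaluable),
        non_evaluable=non_eval,
        excluded_rows=dict(study.exclusions),
        n_records=len(records),
        warnings=list(study.warnings),
        error=len(records) == 0,
    )
    assert report.n_evaluable + report.n_non_evaluable == report.n_subjects
    return report


def load_study(
    path: str | Path,
    mapping_path: str | Path | None = None,
    cfg: EdishConfig | None = None,
    subjects_path: str | Path | None = None,
) -> Study:
    """Read, detect/map and normalize one delimited lab table."""
    raw = read_table(path)
    mapping = mapping_from_file(mapping_path) if mapping_path else None
    subject_table = read_table(subjects_path) if subjects_path else None
    return normalize(raw, mapping=mapping, cfg=cfg, subject_table=subject_table)
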