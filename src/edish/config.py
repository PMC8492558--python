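"""Configuration objects, error types and logging setup.

Every tunable threshold of the analysis lives here so that one
:class:`EdishConfig` (plus an optional :class:`PAltConstants` block) fully
determines the behaviour of the derive/classify/report stages.  Defaults
follow the conventional Hy's Law cut points (ALT >= 3x ULN, total bilirubin
>= 2x ULN) and the CIOMS R-ratio boundaries (<= 2 cholestatic,
>= 5 hepatocellular).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

logger = logging.getLogger("edish")

#: canonical hepatic panel analytes
ANALYTES = ("ALT", "AST", "ALP", "TB")

#: shipped synonym dictionary mapping source lab codes to canonical analytes;
#: user mappings may extend or override it.
DEFAULT_ANALYTE_SYNONYMS: dict[str, str] = {
    "ALT": "ALT", "SGPT": "ALT", "ALAT": "ALT", "L_ALT": "ALT",
    "AST": "AST", "SGOT": "AST", "ASAT": "AST", "L_AST": "AST",
    "ALP": "ALP", "ALKPH": "ALP", "ALK": "ALP", "ALKPHOS": "ALP",
    "TB": "TB", "BILI": "TB", "TBILI": "TB", "BILITOT": "TB", "TOTBILI": "TB",
}

X_AXIS_MODES = ("fold_uln", "fold_baseline", "nr")
POINT_SIZE_MEASURES = ("none", "alp_fold", "r_ratio")
PATTERN_BASES = ("r", "nr")
RATIO_BASES = ("visit", "peak")
DEDUP_POLICIES = ("max", "first", "mean")


class EdishError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EdishError):
    """A configuration value or binding is missing or invalid."""


class DataValidationError(EdishError):
    """The input data cannot support the requested analysis."""


class SubjectNotFoundError(EdishError, KeyError):
    """A subject id was requested that is not present in the study."""


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


@dataclass(frozen=True)
class PAltConstants:
    """Constants of the released-ALT mass-balance estimate of hepatocyte loss.

    ``P_ALT = 100 * (peak_alt - baseline_alt) * distribution_volume_l /
    hepatic_alt_capacity``, clipped to [0, 100].

    Defaults are calibration-dependent and deliberately conservative: a
    vascular distribution volume of 3 L (plasma) and a whole-liver ALT
    capacity of 30,000 U, i.e. complete hepatocyte loss would correspond to
    a ~10,000 U/L rise of serum ALT.  Both are configuration, not code.
    """

    distribution_volume_l: float = 3.0
    hepatic_alt_capacity: float = 30000.0

    def __post_init__(self) -> None:
        if self.distribution_volume_l <= 0:
            raise ConfigurationError("p_alt.distribution_volume_l must be > 0")
        if self.hepatic_alt_capacity <= 0:
            raise ConfigurationError("p_alt.hepatic_alt_capacity must be > 0")


@dataclass(frozen=True)
class EdishConfig:
    """All thresholds, axis modes and display/window settings of the analysis.

    Parameters
    ----------
    alt_fold_threshold, tb_fold_threshold:
        Quadrant cut points on peak ALT fold-ULN (x) and peak total-bilirubin
        fold-ULN (y).  Defaults 3 and 2 follow the Hy's Law convention; both
        are dynamic to accommodate e.g. oncology settings.
    nr_threshold:
        x-axis cut point used instead of ``alt_fold_threshold`` when
        ``x_axis_mode == "nr"`` (the nR-modified approach); default 5.
    x_axis_mode:
        ``fold_uln`` (classic eDISH), ``fold_baseline`` (both axes as fold
        change from subject baseline) or ``nr`` (x = subject nR ratio).
    peak_window_days:
        Window on ``|day(peak ALT) - day(peak TB)|`` used for the
        time-separation colour coding (``within_window``).
    hepatocellular_cut, cholestatic_cut:
        R/nR boundaries of the injury pattern (>= 5 hepatocellular,
        <= 2 cholestatic, in between mixed); inclusivity configurable.
    pattern_basis:
        ``r`` uses ALT in the ratio numerator, ``nr`` uses max(ALT, AST).
    ratio_basis:
        ``visit`` evaluates the subject-level pattern ratio at the day of the
        peak numerator fold (same-day ALP required); ``peak`` divides peak
        folds that may come from different days.
    dedup_policy:
        How duplicate (subject, analyte, day) rows collapse during ingest.
    study_uln:
        Optional per-analyte fallback ULN used when a record lacks one.
    adam_range_var:
        Which ADaM reference-range variable to prefer (ANRHI or A1HI).
    """

    alt_fold_threshold: float = 3.0
    tb_fold_threshold: float = 2.0
    nr_threshold: float = 5.0
    x_axis_mode: str = "fold_uln"
    peak_window_days: int = 30
    point_size_measure: str = "none"
    pattern_basis: str = "r"
    ratio_basis: str = "visit"
    hepatocellular_cut: float = 5.0
    cholestatic_cut: float = 2.0
    boundary_inclusive: bool = True
    dedup_policy: str = "max"
    study_uln: Mapping[str, float] | None = None
    adam_range_var: str = "ANRHI"
    locf_hysteresis: bool = True
    log_axes: bool = True
    group_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for key in ("alt_fold_threshold", "tb_fold_threshold", "nr_threshold",
                    "hepatocellular_cut", "cholestatic_cut"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be > 0")
        if self.peak_window_days < 0:
            raise ConfigurationError("peak_window_days must be >= 0")
        if self.x_axis_mode not in X_AXIS_MODES:
            raise ConfigurationError(
                f"x_axis_mode must be one of {X_AXIS_MODES}")
        if self.point_size_measure not in POINT_SIZE_MEASURES:
            raise ConfigurationError(
                f"point_size_measure must be one of {POINT_SIZE_MEASURES}")
        if self.pattern_basis not in PATTERN_BASES:
            raise ConfigurationError(f"pattern_basis must be one of {PATTERN_BASES}")
        if self.ratio_basis not in RATIO_BASES:
            raise ConfigurationError(f"ratio_basis must be one of {RATIO_BASES}")
        if self.dedup_policy not in DEDUP_POLICIES:
            raise ConfigurationError(f"dedup_policy must be one of {DEDUP_POLICIES}")
        if self.adam_range_var not in ("ANRHI", "A1HI"):
            raise ConfigurationError("adam_range_var must be ANRHI or A1HI")
        if self.study_uln is not None:
            object.__setattr__(self, "study_uln", dict(self.study_uln))
            for k, v in self.study_uln.items():
                if k not in ANALYTES:
                    raise ConfigurationError(f"study_uln key {k!r} not a canonical analyte")
                if v <= 0:
                    raise ConfigurationError(f"study_uln[{k!r}] must be > 0")
        if isinstance(self.group_columns, list):
            object.__setattr__(self, "group_columns", tuple(self.group_columns))

    @property
    def x_threshold(self) -> float:
        """Effective x-axis threshold for the active axis mode."""
        return self.nr_threshold if self.x_axis_mode == "nr" else self.alt_fold_threshold


@dataclass
class RunConfig:
    """Resolved top-level configuration of one pipeline run."""

    input_path: str | None = None
    mapping_path: str | None = None
    subjects_path: str | None = None
    output_path: str = "edish_report.html"
    tables_dir: str | None = None
    log_level: str = "INFO"
    timestamp: bool = False
    seed: int | None = None
    edish: EdishConfig = field(default_factory=EdishConfig)
    p_alt: PAltConstants = field(default_factory=PAltConstants)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["edish"] = dataclasses.asdict(self.edish)
        d["edish"]["group_columns"] = list(self.edish.group_columns)
        d["p_alt"] = dataclasses.asdict(self.p_alt)
        return d


def _check_unknown(given: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for key in given:
        if key not in allowed:
            raise ConfigurationError(f"unknown configuration key {key!r} in {where}")


def config_from_dict(data: Mapping[str, Any] | None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a (possibly empty) mapping.

    Unknown keys are rejected by name; omitted blocks get defaults.
    """
    data = dict(data or {})
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    _check_unknown(data, top_fields, "top level")

    edish_block = dict(data.pop("edish", {}) or {})
    _check_unknown(edish_block, {f.name for f in dataclasses.fields(EdishConfig)}, "edish")
    palt_block = dict(data.pop("p_alt", {}) or {})
    _check_unknown(palt_block, {f.name for f in dataclasses.fields(PAltConstants)}, "p_alt")

    cfg = RunConfig(
        **data,
        edish=EdishConfig(**edish_block),
        p_alt=PAltConstants(**palt_block),
    )
    return cfg


def load_config(path: str) -> RunConfig:
    """Load a YAML (or JSON-subset) run configuration file.

    The fully resolved configuration is echoed to the log so a run is
    auditable from its log alone.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ConfigurationError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config {path} must be a mapping, got {type(raw).__name__}")
    cfg = config_from_dict(raw)
    logger.info("resolved configuration:\n%s", yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return cfg


def apply_overrides(cfg: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply ``--set key=value`` scalar overrides (dotted keys reach blocks)."""
    data = cfg.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ConfigurationError(f"override {item!r} is not of the form key=value")
        key, _, value = item.partition("=")
        parsed = yaml.safe_load(value)
        target: Any = data
        parts = key.strip().split(".")
        for part in parts[:-1]:
            if not isinstance(target, dict) or part not in target:
                raise ConfigurationError(f"unknown configuration key {key!r} in --set")
            target = target[part]
        if not isinstance(target, dict) or parts[-1] not in target:
            raise ConfigurationError(f"unknown configuration key {key!r} in --set")
        target[parts[-1]] = parsed
    return config_from_dict(data)
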