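"""Synthetic clinical-trial hepatic lab panels with known injury phenotypes.

Simulates per-visit ALT/AST/ALP/TB panels for a trial population with a
designed mix of liver-injury phenotypes, and emits the data in the SDTM-like
and ADaM-like dialects the ingest module reads, together with truth labels
(:func:`simulate_study` returns a ``SimTruth`` table).  Every phenotype's
excursion is designed so its defining inequalities hold with a >= 1.2x
margin at zero measurement noise, which makes pipeline recovery of the
designed labels a sharp end-to-end test.

Injury kinetics are piecewise log-linear rise from an onset day to a designed
peak fold at a peak day, then exponential decay back toward baseline — the
shape of a typical hepatocellular injury time course.  Baselines are drawn
lognormally around 0.6x ULN and clipped into the normal range, so baseline
variation is present even in noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigurationError, EdishConfig
from .ingest import RECORD_COLUMNS, Study

PHENOTYPE_ORDER = ("normal", "hys_law", "temples", "hyperbili", "cholestatic", "mixed")

#: designed excursions per phenotype: analyte -> (peak fold-ULN, onset day,
#: peak day, decay half-life in days).  Peak folds carry >= 1.2x margin over
#: the inequalities that define the phenotype (e.g. Hy's Law needs ALT >= 3,
#: TB >= 2, R >= 5: designed ALT fold 6 gives R >= 6.3 even at the highest
#: allowed ALP baseline).
PHENOTYPES: dict[str, dict[str, tuple[float, int, int, float]]] = {
    "normal": {},
    "hys_law": {"ALT": (6.0, 4, 15, 10.0), "AST": (4.8, 4, 15, 10.0),
                "TB": (2.4, 8, 22, 12.0)},
    "temples": {"ALT": (6.0, 4, 15, 10.0), "AST": (4.8, 4, 15, 10.0)},
    "hyperbili": {"TB": (2.4, 8, 22, 12.0)},
    "cholestatic": {"ALP": (2.0, 4, 15, 14.0)},
    "mixed": {"ALT": (3.6, 4, 15, 10.0), "AST": (2.88, 4, 15, 10.0),
              "ALP": (1.2, 4, 15, 14.0)},
}

DEFAULT_ULN = {"ALT": 40.0, "AST": 40.0, "ALP": 120.0, "TB": 1.2}
DEFAULT_SCHEDULE = (-7, 1, 8, 15, 22, 29, 36, 43, 50, 57)
DEFAULT_MIX = {"normal": 0.835, "hys_law": 0.015, "temples": 0.025,
               "hyperbili": 0.025, "cholestatic": 0.05, "mixed": 0.05}

SDTM_CODES = {"ALT": "ALT", "AST": "AST", "ALP": "ALP", "TB": "BILI"}
ADAM_CODES = {"ALT": "ALT", "AST": "AST", "ALP": "ALP", "TB": "TBILI"}


@dataclass(frozen=True)
class SimSpec:
    """Design of one simulated study.

    ``mix`` maps phenotypes to counts (ints summing to ``n_subjects``) or to
    proportions (floats summing to 1; each subject then draws its phenotype
    from its own random substream, so earlier subjects are unchanged when
    ``n_subjects`` grows).  ``noise_sd`` is the lognormal measurement-noise
    standard deviation on the log scale; ``baseline_log_sd`` controls
    between-subject baseline variation (always on, clipped into the normal
    range).
    """

    n_subjects: int = 200
    mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    uln: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ULN))
    noise_sd: float = 0.1
    baseline_log_sd: float = 0.1
    baseline_center: float = 0.6
    baseline_clip: tuple[float, float] = (0.35, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mix", dict(self.mix))
        object.__setattr__(self, "schedule", tuple(self.schedule))
        object.__setattr__(self, "uln", dict(self.uln))
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.mix) - set(PHENOTYPE_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown phenotype(s) in mix: {sorted(unknown)}")
        vals = list(self.mix.values())
        if not vals:
            raise ConfigurationError("mix must not be empty")
        if all(float(v).is_integer() for v in vals) and sum(vals) == self.n_subjects:
            object.__setattr__(self, "_mix_kind", "counts")
        elif abs(sum(vals) - 1.0) < 1e-9:
            object.__setattr__(self, "_mix_kind", "proportions")
        else:
            raise ConfigurationError(
                "mix must be integer counts summing to n_subjects or "
                "proportions summing to 1")
        days = self.schedule
        if any(d == 0 for d in days):
            raise ConfigurationError("schedule must not contain day 0")
        if list(days) != sorted(set(days)):
            raise ConfigurationError("schedule days must be strictly increasing")
        if not any(d <= 1 for d in days):
            raise ConfigurationError("schedule needs at least one baseline day (<= 1)")
        if sum(d > 1 for d in days) < 2:
            raise ConfigurationError("schedule needs at least two post-baseline days")

    @property
    def mix_kind(self) -> str:
        return getattr(self, "_mix_kind")


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, index-stable random stream for one subject."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def designed_fold(phenotype: str, analyte: str, baseline_fold: float, day: int) -> float:
    """Noise-free designed fold-ULN of one analyte at one study day."""
    exc = PHENOTYPES[phenotype].get(analyte)
    if exc is None:
        return baseline_fold
    peak_fold, onset, peak_day, half_life = exc
    if day <= onset:
        return baseline_fold
    if day <= peak_day:
        frac = (day - onset) / (peak_day - onset)
        return float(np.exp(np.log(baseline_fold)
                            + frac * (np.log(peak_fold) - np.log(baseline_fold))))
    return baseline_fold + (peak_fold - baseline_fold) * 2.0 ** (-(day - peak_day) / half_life)


def designed_series(phenotype: str, baselines: Mapping[str, float],
                    schedule: tuple[int, ...]) -> pd.DataFrame:
    """Day x analyte table of designed (noise-free) folds."""
    if phenotype not in PHENOTYPES:
        raise ConfigurationError(f"unknown phenotype {phenotype!r}")
    data = {a: [designed_fold(phenotype, a, baselines[a], d) for d in schedule]
            for a in DEFAULT_ULN}
    return pd.DataFrame(data, index=pd.Index(schedule, name="study_day"))


def _designed_truth(phenotype: str, design: pd.DataFrame,
                    cfg: EdishConfig) -> dict:
    """Quadrant and injury-pattern labels implied by the designed curves.

    Applies the same analysis conventions as the pipeline defaults
    (treatment-emergent peaks, earliest-day ties, visit-basis R at the peak
    ALT day) directly to the noise-free design, with plain array scans.
    """
    post = design[design.index > 1]
    truth: dict = {}
    for a in DEFAULT_ULN:
        folds = post[a].to_numpy()
        i = int(np.argmax(folds))  # argmax returns the first (earliest) max
        truth[f"{a}_peak_fold_design"] = float(folds[i])
        truth[f"{a}_peak_day_design"] = int(post.index[i])
    alt, tb = truth["ALT_peak_fold_design"], truth["TB_peak_fold_design"]
    if alt >= cfg.alt_fold_threshold and tb >= cfg.tb_fold_threshold:
        quad = "possible_hys_law"
    elif alt >= cfg.alt_fold_threshold:
        quad = "temples_corollary"
    elif tb >= cfg.tb_fold_threshold:
        quad = "hyperbilirubinemia"
    else:
        quad = "within_range"
    truth["quadrant_design"] = quad
    day = truth["ALT_peak_day_design"]
    ratio = post.loc[day, "ALT"] / post.loc[day, "ALP"]
    if ratio >= cfg.hepatocellular_cut:
        pattern = "hepatocellular"
    elif ratio <= cfg.cholestatic_cut:
        pattern = "cholestatic"
    else:
        pattern = "mixed"
    truth["pattern_design"] = pattern
    truth["pattern_ratio_design"] = float(ratio)
    return truth


def simulate_subject(phenotype: str, spec: SimSpec,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Simulate one subject's per-visit panel; returns (records, truth row).

    Draw order from the subject stream is fixed (baselines, attributes,
    measurement noise) so outputs are reproducible.
    """
    if phenotype not in PHENOTYPES:
        raise ConfigurationError(f"unknown phenotype {phenotype!r}")
    lo, hi = spec.baseline_clip
    baselines = {a: float(np.clip(
        spec.baseline_center * np.exp(rng.normal(0.0, spec.baseline_log_sd)), lo, hi))
        for a in DEFAULT_ULN}
    arm = "DRUG" if rng.random() < 0.5 else "PLACEBO"
    sex = "F" if rng.random() < 0.5 else "M"
    design = designed_series(phenotype, baselines, spec.schedule)
    noise = rng.normal(0.0, 1.0, size=design.shape) if spec.noise_sd > 0 else None

    rows = []
    for j, day in enumerate(spec.schedule):
        for k, analyte in enumerate(DEFAULT_ULN):
            fold = design.iloc[j, design.columns.get_loc(analyte)]
            if noise is not None:
                fold = fold * float(np.exp(spec.noise_sd * noise[j, k]))
            uln = float(spec.uln[analyte])
            rows.append((analyte, fold * uln, uln, day))
    records = pd.DataFrame(rows, columns=["analyte", "value", "uln", "study_day"])
    truth = {"phenotype": phenotype, "arm": arm, "sex": sex,
             **{f"{a}_baseline_fold": baselines[a] for a in DEFAULT_ULN},
             **_designed_truth(phenotype, design, EdishConfig())}
    return records, truth


def _phenotype_for(spec: SimSpec, index: int, rng: np.random.Generator) -> str:
    if spec.mix_kind == "counts":
        expanded = [p for p in PHENOTYPE_ORDER for _ in range(int(spec.mix.get(p, 0)))]
        return expanded[index]
    phenos = [p for p in PHENOTYPE_ORDER if p in spec.mix]
    probs = np.array([spec.mix[p] for p in phenos], dtype=float)
    return phenos[int(rng.choice(len(phenos), p=probs / probs.sum()))]


def simulate_study(spec: SimSpec) -> tuple[Study, pd.DataFrame]:
    """Simulate a whole study; returns the Study and the SimTruth table.

    Deterministic for a fixed seed; each subject uses an independent
    substream keyed by its index, so increasing ``n_subjects`` leaves earlier
    subjects byte-identical.
    """
    all_records = []
    truth_rows = []
    attrs = {}
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i)
        sid = f"S{i + 1:04d}"
        # phenotype draw consumes from the same stream before panel draws
        phenotype = _phenotype_for(spec, i, rng)
        panel, truth = simulate_subject(phenotype, spec, rng)
        panel.insert(0, "subject_id", sid)
        all_records.append(panel)
        attrs[sid] = {"ARM": truth.pop("arm"), "SEX": truth.pop("sex")}
        truth_rows.append({"subject_id": sid, **truth})
    records = pd.concat(all_records, ignore_index=True)
    records["baseline_flag"] = False
    records = (records.sort_values(["subject_id", "analyte", "study_day"])
               .reset_index(drop=True)[list(RECORD_COLUMNS)])
    attributes = pd.DataFrame.from_dict(attrs, orient="index").sort_index()
    attributes.index.name = "subject_id"
    truth_df = pd.DataFrame(truth_rows).set_index("subject_id").sort_index()
    study = Study(records=records, subject_attributes=attributes,
                  provenance={"dialect": "synthetic", "seed": spec.seed})
    return study, truth_df


def write_dialect(study: Study, dialect: str, out_path: str | Path) -> Path:
    """Write a Study as a delimited SDTM-like or ADaM-like table.

    Emitted columns exactly match the corresponding dialect signature, so
    normalizing the file reproduces the input records.
    """
    rec = study.records
    if dialect == "sdtm":
        out = pd.DataFrame({
            "USUBJID": rec["subject_id"],
            "LBTESTCD": rec["analyte"].map(SDTM_CODES),
            "LBSTRESN": rec["value"],
            "LBSTNRHI": rec["uln"],
            "LBDY": rec["study_day"],
        })
    elif dialect == "adam":
        out = pd.DataFrame({
            "USUBJID": rec["subject_id"],
            "PARAMCD": rec["analyte"].map(ADAM_CODES),
            "AVAL": rec["value"],
            "ANRHI": rec["uln"],
            "ADY": rec["study_day"],
        })
    else:
        raise ConfigurationError(f"unsupported dialect {dialect!r}")
    out_path = Path(out_path)
    out.to_csv(out_path, index=False)
    return out_path


def write_truth(truth: pd.DataFrame, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    truth.to_csv(out_path)
    return out_path


def write_subjects(study: Study, out_path: str | Path) -> Path:
    """Write the per-subject attribute table (USUBJID + attributes)."""
    out_path = Path(out_path)
    attrs = study.subject_attributes
    if attrs is None:
        attrs = pd.DataFrame(index=pd.Index(study.subjects(), name="subject_id"))
    attrs = attrs.rename_axis("USUBJID")
    attrs.to_csv(out_path)
    return out_path


def phenotype_recovery(truth: pd.DataFrame, labelled: pd.DataFrame) -> float:
    """Fraction of subjects whose pipeline quadrant and injury pattern both
    match the designed truth labels."""
    merged = labelled.merge(truth, left_on="subject_id", right_index=True)
    ok = ((merged["quadrant"] == merged["quadrant_design"])
          & (merged["injury_pattern"] == merged["pattern_design"]))
    return float(ok.mean())
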