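# Methods

## The eDISH analysis

The package screens longitudinal hepatic panels (ALT, AST, ALP, total
bilirubin) for drug-induced liver injury signals. All analysis is performed
on unitless fold changes: per record, fold-ULN = value / ULN; optionally
fold-baseline = value / baseline value. ULNs are assumed consistent within
(study, analyte); no unit conversion is attempted (folds are unit-free), and
a heuristic warning fires when a ULN varies more than 2× within one analyte,
the usual symptom of mixed units or mixed labs.

Conventions, all configurable through `EdishConfig`:

- **Study day** is CDISC 1-based with no day 0; day ≤ 1 is pre/at first
  dose. Baseline per (subject, analyte) is the record at the latest day ≤ 1;
  an explicit baseline flag from the column mapping overrides. Peaks are
  treatment-emergent: taken over days > 1 only, with ties broken to the
  earliest day so the peak-time separation is deterministic.
- **Quadrants.** x = peak ALT fold-ULN (or peak fold-baseline, or the
  subject nR ratio, per `x_axis_mode`), y = peak TB fold-ULN. Cut points
  default to the Hy's Law convention x ≥ 3, y ≥ 2 (nR mode: x ≥ 5) and are
  inclusive on the flagged side: a subject exactly at a threshold is
  flagged. Quadrant membership uses peaks that may come from different
  days — classic eDISH; temporal concordance is carried separately by
  `within_window` = (|day(peak ALT) − day(peak TB)| ≤ `peak_window_days`,
  default 30 days), which also drives the point colouring in the report.
- **R/nR and injury pattern.** Per visit, R = ALT fold / ALP fold and
  nR = max(ALT, AST fold) / ALP fold, defined only where a same-day positive
  ALP fold exists (when AST fold ≤ ALT fold, nR = R by construction). The
  CIOMS-style pattern uses two breakpoints: ratio ≥ 5 hepatocellular,
  ≤ 2 cholestatic, strictly between mixed; absent ratio → indeterminate;
  boundary inclusion configurable. The subject-level pattern ratio is, by
  default, the visit ratio at the day of the peak numerator fold
  (`ratio_basis="visit"`); a peak-basis variant (ratio of peak folds,
  possibly different days) is provided as `ratio_basis="peak"` since both
  conventions are in use.
- **P_ALT** estimates percent hepatocyte loss from the serum-ALT rise by a
  released-enzyme mass balance:
  `P_ALT = 100 · (peak ALT − baseline ALT) · V_d / C`, clipped to [0, 100]
  and 0 when the peak does not exceed baseline. The defaults, V_d = 3 L
  (plasma volume) and whole-liver ALT capacity C = 30,000 U (complete loss
  ≈ a 10,000 U/L rise over 3 L), are explicitly calibration-dependent
  configuration (`PAltConstants`), not code; users with a preferred
  calibration should override them.
- **Hysteresis path.** The ALT-vs-TB trajectory is defined at every day
  where either analyte was observed, starting at the first day both have
  been observed; days missing one analyte carry the last observation forward
  (LOCF; configurable to drop incomplete days). LOCF keeps the path defined
  without inventing interpolated values.

### Deduplication and exclusions

Duplicate (subject, analyte, day) rows collapse to the maximum value by
default — conservative for safety screening — configurable to first/mean.
Rows with unmappable analyte codes, non-numeric results, missing/invalid
ULN (after an optional per-analyte study-level fallback), day 0, or negative
results are excluded and counted by reason; a subject without post-baseline
ALT and TB is retained but marked non-evaluable. The validation report
always satisfies evaluable + non-evaluable = total.

## Dialect handling

SDTM LB-like tables are recognized by the column signature
{USUBJID, LBTESTCD, LBSTRESN, LBSTNRHI, LBDY}; ADaM ADLB-like by
{USUBJID, PARAMCD, AVAL, ADY} plus ANRHI or A1HI (ANRHI preferred by
default, configurable). When both signatures are present the tie resolves
to ADaM — analysis-ready data trumps tabulation data — and the tie is
logged. Any other table is normalized through a user-supplied YAML mapping
(column bindings plus an analyte-code dictionary; a shipped synonym table
covers common codes such as SGPT/ALAT → ALT, BILI/TBILI → TB). Numeric
fields are parsed with correctly-rounded `float()` so that text round trips
(write → read) are bit-exact.

## Numerical conventions

Derived folds and ratios are defined at **9 significant digits**
(`derive.SIG_DIGITS`). Laboratory assays carry at most 3-4 significant
digits, so the quantization is far below scientific resolution; its purpose
is well-definedness: at this precision derived values are exactly invariant
under a common positive rescaling of all values and ULNs (i.e. a unit
change), which raw double-precision division is not (the two roundings of
`value·c` and `ULN·c` shift roughly a third of quotients by one ulp). Peak
selection operates on the quantized folds, so peak days, tie-breaks and all
downstream labels share the invariance. P_ALT is intentionally
unit-bearing (U/L) and is not scale-invariant.

The interactive report is rendered by a small SVG charting runtime written
inline into the document together with one JSON payload; the exported file
contains no external script/style/font/image references and renders with
networking disabled. Tooltip strings are formatted once (`%.10g`) from the
same derived values the exported tables carry, so displayed numbers can
never drift from the tables. With the timestamp switch off (default),
rebuilding from identical inputs is byte-identical.

## The synthetic trial simulator

`edish.synthetic` emulates per-visit hepatic panels with designed injury
phenotypes so the pipeline is testable end-to-end without external data.
Defaults (all configurable in `SimSpec`):

- ULNs: ALT 40 U/L, AST 40 U/L, ALP 120 U/L, TB 1.2 mg/dL — conventional
  reference values that only make the synthetic data concrete.
- Visit schedule: days (−7, 1, 8, 15, 22, 29, 36, 43, 50, 57) — a screening
  visit, a day-1 baseline and eight post-baseline visits, a typical phase-2
  rhythm.
- Baselines: lognormal around 0.6×ULN with log-SD 0.1, clipped into
  [0.35, 0.95]×ULN. Baseline variation is part of the design and present
  even at zero noise; the clip guarantees noise-free normals stay within
  the normal range for any seed.
- Measurement noise: multiplicative lognormal with log-SD 0.1 (≈10%
  CV), a realistic combined analytic + short-term biological variability
  for these analytes.
- Kinetics: each injury phenotype superimposes a piecewise log-linear rise
  from an onset day to a designed peak fold at a peak day, then exponential
  decay (half-life 10-14 days) back toward baseline — the shape of a
  typical hepatocellular injury time course, with the peak analytically
  controlled. ALT/AST/ALP peak at day 15, TB at day 22, giving a realistic
  7-day enzyme-to-bilirubin lag.
- Designed peak folds clear every phenotype-defining inequality with ≥1.2×
  margin at zero noise even at the extremes of the baseline clip (e.g. the
  Hy's Law design uses ALT fold 6 so the visit R exceeds 5×1.2 at the
  highest allowed ALP baseline). Consequently noise-free data are classified
  perfectly for any seed, and recovery degrades gracefully with noise
  (~99.8% at the default noise in a 1000-subject study).
- Phenotype mix: default proportions 83.5% normal, 1.5% possible Hy's Law,
  2.5% Temple's, 2.5% hyperbilirubinemia, 5% cholestatic, 5% mixed —
  rare-event proportions typical of a hepatotoxic signal-positive program.
  Integer-count mixes are allocated deterministically; proportion mixes are
  drawn per subject from its own substream.
- Reproducibility: each subject consumes an independent RNG substream keyed
  by (master seed, subject index), so growing the population leaves earlier
  subjects byte-identical, and fixed seeds yield byte-identical dialect
  files.

Truth labels (`SimTruth`) carry, per subject, the phenotype, designed peak
folds/days, and the quadrant/pattern implied by the noise-free designed
curves under the default analysis conventions, computed by direct array
scans at simulation time — not by running the pipeline.

What the simulator does **not** emulate: missed visits and dropout,
unscheduled visits, assay censoring (values below quantitation), covariate-
dependent injury risk, rechallenge, or drug-specific pharmacokinetics.
Passing tests therefore demonstrate correctness of the derivations and
classification logic under clean longitudinal sampling, not robustness to
every messiness of real trial data (the exclusion accounting in ingest is
exercised by dedicated fixtures instead).

## Problem sizes

The test suite and the acceptance script use a 200-subject designed-mix
study for classification and report checks, 25 random studies of ≤ 50
subjects for brute-force oracle equivalence, and one 1000-subject study for
the noisy-recovery regression — sizes at which every derived quantity is
also checkable by an independent full-scan reference implementation.

## Known limitations

- No causality scoring (RUCAM), no adjudication logic, no between-arm
  inference on quadrant proportions.
- P_ALT is a first-order mass balance; it ignores ALT clearance kinetics
  and so understates loss for slow rises.
- SAS transport ingest is an extension point, not implemented; input is
  delimited text.
- The report's interactivity targets current browsers; it degrades (static
  figure, no animation) without JavaScript.
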