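# edish

Signal detection for drug-induced liver injury (DILI) from clinical-trial
laboratory data: an open reimplementation of the interactive eDISH
(Evaluation of Drug-Induced Serious Hepatotoxicity) analysis as a Python
library plus CLI, for safety reviewers, statisticians and data monitoring
committees who need to triage hepatic lab panels during ongoing trials.

## What it computes

For each subject with longitudinal ALT, AST, ALP and total-bilirubin (TB)
measurements, each with its upper limit of normal (ULN):

- **fold-ULN** `value / ULN` and **fold-baseline** `value / baseline` per
  visit (baseline = latest record at study day ≤ 1, or an explicit flag);
- **R ratio** `(ALT/ULN) / (ALP/ULN)` and **nR ratio**
  `max(ALT, AST fold) / (ALP fold)` per visit, and the derived injury
  pattern: R ≥ 5 hepatocellular, R ≤ 2 cholestatic, between mixed;
- **treatment-emergent peaks** (study day > 1, ties to the earliest day),
  the **peak-time separation** `|day(peak ALT) − day(peak TB)|` against a
  configurable window, and **P_ALT**, a released-ALT mass-balance estimate
  of percent hepatocyte loss;
- the **eDISH quadrant** from peak ALT fold (x) and peak TB fold (y) at the
  Hy's Law cut points (defaults x ≥ 3, y ≥ 2, both configurable; axes
  switchable to fold-baseline or to the nR-modified approach):
  *possible Hy's Law* (both), *Temple's Corollary* (ALT only),
  *hyperbilirubinemia* (TB only), *within range*;
- a **triage table** ordered by quadrant severity, grouped **quadrant
  counts**, and a fully **self-contained interactive HTML report** (scatter
  with threshold lines, click-through participant profiles, R-ratio
  companion series and an animated ALT-vs-TB hysteresis path; no external
  network references).

Input is delimited text in SDTM LB-like or ADaM ADLB-like form
(auto-detected by column signature) or any table plus a small YAML column
mapping. A synthetic trial simulator with designed injury phenotypes
(`edish.synthetic`) makes the entire pipeline testable without real data.

## Worked example

```python
from edish import (SimSpec, simulate_study, subject_summary,
                   assign_quadrants, quadrant_counts, triage_table)

study, truth = simulate_study(SimSpec(n_subjects=200, seed=7))
summaries = assign_quadrants(subject_summary(study))
print(quadrant_counts(summaries))
```

```
                    count
quadrant
possible_hys_law        4
temples_corollary      15
hyperbilirubinemia      3
within_range          178
```

Four subjects have peak ALT ≥ 3×ULN together with peak TB ≥ 2×ULN — the
possible Hy's Law cases a reviewer would escalate first. The triage table
puts them on top, worst ALT elevation first:

```
subject_id          quadrant  ALT_peak_fold  ALT_peak_day  TB_peak_fold  TB_peak_day  peak_time_separation_days  within_window injury_pattern  p_alt_percent
     S0081  possible_hys_law       6.667740            15      2.435690           22                          7           True hepatocellular       2.372582
     S0198  possible_hys_law       6.304803            15      2.547785           22                          7           True hepatocellular       2.332409
```

`S0081` peaked at 6.7×ULN ALT on day 15 and 2.4×ULN bilirubin on day 22; the
7-day separation is inside the default 30-day concordance window, the R
ratio at the ALT peak marks a hepatocellular pattern, and the ALT rise
corresponds to an estimated 2.4% hepatocyte loss.

From the shell:

```sh
edish simulate --n 200 --seed 7 --out-dir sim     # SDTM + ADaM files + truth
edish run sim/lab_sdtm.csv --subjects sim/subjects.csv \
    --out report.html --tables-dir tables         # interactive report + tables
edish check sim/lab_adam.csv                      # validation report only
edish run sim/lab_sdtm.csv --set edish.alt_fold_threshold=5 --out onc.html
```

`report.html` is a single self-contained file: open it in any browser (no
network needed), hover points for the derived values, click one for the
participant profile and hysteresis animation, and filter by any subject
attribute supplied.

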