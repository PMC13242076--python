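# toxconcord

Concordance analysis between clinician-graded treatment toxicities and
patient-reported symptom severity in two-arm oncology trials.

Clinicians grade adverse events with the CTCAE (ordinal 0 = none to
4 = life-threatening); patients answer EORTC QLQ-C30/BR23 symptom items
on a 4-point Likert scale (1 "not at all" ... 4 "very much").  The two
instruments systematically disagree — clinicians tend to under-grade
the symptom burden patients actually report — and quantifying that
disagreement requires scoring, harmonizing, and comparing the two
scales correctly.  `toxconcord` implements that pipeline for the six
symptom domains with direct conceptual overlap between the instruments
(diarrhea, nausea, vomiting, mucositis/dry mouth, pain, fatigue), plus
a synthetic trial generator with a known discordance mechanism so the
entire analysis is testable without access to per-patient trial data.

## What it computes

* **EORTC scale scoring** — single items used directly; multi-item
  scales (pain: 2 items, fatigue: 3 items) averaged under the half-rule
  (score missing unless ≥ half the items are answered), linearly
  transformed to 0–100 (`(raw − 1)/3 × 100`), and re-categorized into
  four severity levels (nearest anchor, ties toward higher severity).
* **Harmonization** — CTCAE grades 3/4 collapsed; agreement defined by
  the fixed pairing grade 0 ↔ score 1, 1 ↔ 2, 2 ↔ 3, 3/4 ↔ 4; each
  matched pair classified as agreement, clinician underreporting, or
  clinician overestimation; binary none-vs-any recoding
  (grade ≥ 1 vs score ≥ 2) for 2×2 analysis.
* **Agreement statistics** — Cohen's kappa in the disagreement-weight
  form κ = 1 − Σd·o / Σd·e with quadratic weights
  d_ij = (i−j)²/(k−1)² on the 4-level scale and unweighted (0/1)
  weights on the binary scale; two-sided asymptotic p-values for
  H₀: κ = 0 from the Fleiss–Cohen–Everitt null variance; conventional
  interpretation bands (≤0.20 no agreement, 0.21–0.39 minimal, …).
* **Discordance tests** — underreport/overestimate rates; exact
  two-sided binomial test for predominance of underreporting among
  discordant pairs (default α = 0.004, multiplicity-adjusted for 12
  symptom × time strata); McNemar's test (continuity-corrected, exact
  fallback for < 25 switches) for mid-to-end change in discordance on
  the paired subset; pooled two-sample z-tests for between-arm
  comparisons (z² equals the Pearson chi-square exactly).
* **Synthetic cohorts** — latent ordinal severities, a clinician
  underreporting/overestimation mechanism defined on the collapsed
  scale, ±1 item noise, item- and visit-level missingness, all with
  closed-form expected summaries by exhaustive enumeration
  (`true_parameters`) for parameter-recovery checks.

## Worked example

Unweighted kappa from a published binary 2×2 (diarrhea, arm A,
mid-treatment: 495 reported by neither, 27 clinician-only, 95
patient-only, 49 both):

```python
import numpy as np
from toxconcord import ContingencyTable, WeightScheme, cohen_kappa

table = ContingencyTable(np.array([[495, 95], [27, 49]]))   # rows: clinician
res = cohen_kappa(table, WeightScheme.UNWEIGHTED)
print(f"kappa = {res.kappa:.2f} ({res.label}), n = {res.n}, p = {res.p_value:.2e}")
```

prints

```
kappa = 0.35 (minimal), n = 666, p = 5.34e-22
```

i.e. even though 82% of the 666 pairs fall on the diagonal, the
chance-corrected agreement is only "minimal", and the null of no
association is overwhelmingly rejected.

Full pipeline on a simulated trial:

```bash
toxconcord simulate --seed 1 --n-per-arm 400 --out sim/
toxconcord analyze --ctcae sim/ctcae.csv --eortc sim/eortc.csv --out report/
```

`report/agreement.csv` then holds one row per arm × time point × domain
(arm A, mid-treatment shown):

```
   domain   n  kappa p_display    label
 diarrhea 369   0.77    <0.001 moderate
   nausea 364   0.71    <0.001 moderate
 vomiting 370   0.84    <0.001   strong
mucositis 369   0.76    <0.001 moderate
     pain 377   0.79    <0.001 moderate
  fatigue 376   0.74    <0.001 moderate
```

and `report/underreport.csv` the directional discordance rates (the
default generator underreports 35% of assessments, partially masked by
floor effects in low-severity domains):

```
   domain  underreport_pct  overestimate_pct
 diarrhea             14.9               3.5
   nausea             26.9               4.9
 vomiting              7.8               4.3
mucositis             27.6               5.7
     pain             23.9               4.5
  fatigue             31.6               4.0
```

The bundle also contains `binary.csv` (2×2 cells + unweighted kappa),
`change.csv` (mid-to-end change with McNemar p), `predominance.csv`
(exact binomial tests) and a `manifest.json` with a config hash —
outputs are byte-identical across repeated runs on the same inputs.

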