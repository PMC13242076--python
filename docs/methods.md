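# Methods

## Instruments and matching

The clinician side is a CTCAE toxicity grade per patient × treatment
arm × time point × symptom domain (ordinal 0–4; grade 5 does not occur
in symptom-level concordance data).  The patient side is one or more
EORTC QLQ-C30/BR23 symptom items per domain on the 1–4 Likert scale.
Six domains are supported, fixed by an a-priori conceptual mapping:
diarrhea, nausea, vomiting and mucositis (dry mouth) map to one item
each; pain to two items (pain intensity, pain interference) and
fatigue to three (need to rest, weakness, tiredness).

Matching is **pairwise per domain and time point**: a pair enters a
given analysis only when both the grade and the scored severity are
present.  The matched n therefore differs legitimately across domains
within the same arm/time stratum.  Listwise deletion across domains
would discard information and is not offered.  Inputs are long-format
CSVs with one record per row; duplicated keys are a hard error and
out-of-range codes (including common missing-data sentinels such as 9
or 99) are rejected rather than silently recoded — a deliberate safety
property for clinical data.

The package takes one grade per patient/time point/domain as input.
Trials that grade per cycle must aggregate upstream (e.g. take the
assessment at the analysis cycle, or the cycle maximum); the choice
genuinely affects results and is not made silently by this package.

## EORTC scoring

Multi-item scales use the standard EORTC convention: the raw score is
the mean of the answered items, computable only when at least
⌈n_items/2⌉ items are answered (the half-rule, which is exactly
equivalent to imputing each missing item with the mean of the answered
ones).  Raw means are linearly transformed to 0–100 by
(raw − 1)/3 × 100.

The four-level re-categorization of transformed scores has no single
published convention, so this package defines one and documents it:
the severity level whose anchor score (0, 33.33, 66.67, 100 — the
images of raw 1–4) is nearest, with ties assigned to the **higher**
severity (conservative toward the patient-reported burden).  It is
implemented as round-half-up on the raw 1–4 mean, which avoids
floating-point boundary artifacts at 50.0 and 83.33 and makes the
single-item and multi-item pathways exactly consistent: a single item
r always re-categorizes to level r.  On the attainable score grid,
midpoint ties occur for 2-item means (raw 1.5, 2.5, 3.5) — whether
from the pain scale or from a fatigue scale with one item missing —
and the rule resolves them upward; fully answered 3-item means are
multiples of 1/3 and never tie.  Functional scales and the
7-point global health item are out of scope (reverse scoring is never
needed for symptom scales).

## Harmonization and concordance classes

CTCAE grades 3 and 4 are collapsed (both are "severe or worse"; the
4-point patient scale cannot distinguish them), giving a 0–3 clinician
scale g aligned with patient severity s by the pairing g + 1 = s.
Each complete pair is classified: agreement (s = g + 1), clinician
underreporting (g + 1 < s), clinician overestimation (g + 1 > s).
A raw grade 4 against severity 4 is agreement by construction, never
overestimation.  Of the 16 collapsed combinations exactly 4 are
agreement, 6 underreporting, 6 overestimation.

The binary recoding is none-vs-any on both sides: clinician grade ≥ 1,
patient severity ≥ 2, yielding the 2×2 cells reported by neither /
clinician only / patient only / both.

## Agreement statistics

Cohen's kappa is computed in the disagreement-weight form

    kappa = 1 − Σ_ij d_ij o_ij / Σ_ij d_ij e_ij

with observed proportions o, independence expectations e_ij = r_i c_j,
and d_ij = 1{i≠j} (unweighted) or (i−j)²/(k−1)² (quadratic, k = 4
levels).  The convention is stated explicitly because texts differ;
this form is algebraically identical to the agreement-weight form.
For k = 2 the quadratic weights coincide with 0/1 weights, so
quadratic kappa on any 2×2 table equals unweighted kappa exactly — a
tested invariant.  Degenerate tables (zero expected disagreement)
raise an explicit error instead of returning 0 or NaN.

P-values test H₀: κ = 0, two-sided, using the large-sample null
standard error of weighted kappa (Fleiss–Cohen–Everitt form) with a
normal reference.  On 2×2 tables the squared statistic reduces to the
uncorrected Pearson chi-square, and on 4×4 tables the asymptotic p
agrees with a label-permutation Monte-Carlo p at n ≈ 200 (both are
tested).  Whether the comparison should be one- or two-sided is a
convention choice; two-sided is implemented.  Samples below n = 30
carry a small-sample flag rather than a different test.

Report rounding follows clinical-journal convention: kappa to 2 dp
(half-up), percentages to 1 dp, interpretation bands applied to the
rounded kappa (≤ 0.20 no agreement, 0.21–0.39 minimal, 0.40–0.59 weak,
0.60–0.79 moderate, 0.80–0.90 strong, > 0.90 almost perfect).

## Discordance tests

* **Predominance**: exact two-sided binomial test on discordant pairs
  of P(underreport | discordant) = ½, summing all outcomes no more
  probable than the observed one.  Default α = 0.004, the
  multiplicity-adjusted threshold for 12 symptom × time strata;
  overridable (`--alpha`).
* **McNemar** (mid-to-end change within arm, restricted to patients
  with complete pairs at both time points): continuity-corrected
  chi-square (|b−c|−1)²/(b+c) on the status-switch counts, 1 df, with
  an exact binomial fallback when b + c < 25; the variant is
  switchable.  Zero switches return p = 1 with a degenerate flag.
  Both the change-in-rate estimates and the test use the paired subset
  (using the full cross-sections for the rates but the paired subset
  for the test would conflate composition change with within-patient
  change).
* **Between-arm comparisons**: pooled-variance two-sample z-test,
  two-sided, no continuity correction by default so that z² equals
  the Pearson chi-square identically (correction available by flag).

## Synthetic trial generator

The generator emulates the structure of a two-arm adjuvant
chemotherapy trial: ~700 patients per arm by default (the order of a
large phase III per-arm cohort), two assessment time points, six
domains.  Per patient × domain × time point: latent severity
s ~ per-domain marginal; clinician grade concordant (g = s − 1) with
probability 1 − u − v, underreported by a 1–3 level depth draw with
probability u (default 0.35, depth distribution 0.65/0.25/0.10),
overestimated one level with probability v (default 0.03, consistent
with overestimation being rare, under 5% of observations); items equal
s with symmetric ±1 noise (default 0.10), clamped to 1–4; items and
whole visits go missing independently (defaults 0.02 and 0.05).  At
end-of-treatment the severity marginals drift one level upward for a
0.15 mass fraction (downward for nausea/vomiting, the
antiemetic-responsive domains), emulating rising cumulative toxicity
with improving emesis control.

Defining the clinician mechanism on the collapsed 0–3 scale makes u
directly comparable to the measured underreport rate; the measured
rate is nonetheless below u because a downgrade from s = 1 is floored
at grade 0, where patient-side noise can still produce an "agreement"
— the enumeration oracle accounts for all of this exactly.

`true_parameters` computes, per stratum, the exact joint distribution
of (collapsed grade, observed severity) conditional on a complete
pair, by enumerating latent severity × mechanism × depth × per-item
noise outcomes × answered-item subsets.  From it: expected
underreport/overestimate rates, binary cell probabilities, expected
quadratic and binary kappa, and the pair-completeness probability
(used to weight strata when pooling).  Degenerate marginals (all mass
on one level) yield an undefined expected kappa, flagged rather than
silenced.

A property worth noting: under independent per-item missingness the
half-rule makes multi-item scales **more** robust than single items,
not less — pain is scorable with probability 1 − m², fatigue with
(1−m)³ + 3m(1−m)², versus 1 − m for a single item.  The missingness
test asserts these closed forms.

What the generator does **not** emulate: correlated severities across
domains or time points within a patient (severities are independent
draws), informative missingness (dropout is independent of severity,
while real end-of-treatment dropout is usually toxicity-related),
per-cycle grade aggregation, and rater effects shared across a site.
Consequently, passing parameter-recovery tests shows the pipeline's
statistics are computed correctly under a known mechanism — it does
not certify the generator as a realistic portrait of trial data.  In
particular, because discordance is generated *conditionally on* the
latent severity, simulated kappas (≈ 0.7–0.8 at the defaults) are far
higher than those observed in real clinician-vs-patient comparisons
(≈ 0.03–0.37), where the two assessments carry largely independent
error; the generator measures mechanism recovery, not realism of
chance-corrected agreement.

All randomness flows from one seeded generator in a documented draw
order, with the same number of variates consumed on every branch, so
cohorts are bit-reproducible and stable under parameter changes that
do not alter the loop structure.

## Problem sizes

Default test and acceptance runs use 2000 patients per arm for
parameter recovery (20 seeds in the test suite; ≈ 45 000 matched pairs
per cohort), 1000 random tables for oracle-equivalence sweeps, and
10⁴ permutations for the p-value cross-check — sizes at which binomial
and Monte-Carlo error are far smaller than the tested tolerances.

## Known limitations

* The four-level categorization rule is this package's documented
  convention; other cut-point choices would change multi-item severity
  levels near band edges.
* Asymptotic kappa p-values are anti-conservative for very sparse
  tables; the permutation cross-check is available for small n.
* Only two analysis time points are modelled; baseline/follow-up
  questionnaires and per-cycle AE ledgers are out of scope.
* Stratification is by arm × time point; arbitrary extra grouping
  columns (e.g. country) can be handled by filtering the input tables
  per group and running the pipeline per subset.
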