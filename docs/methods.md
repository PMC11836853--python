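# Methods

## Phenotyping model

Each phenotyping rule is a triple *(require E83.1, minimum venesection
episodes k, exclusion groups)* applied to per-patient features aggregated
over all of a patient's in-window episodes:

* `has_e831` — any diagnosis position of any episode matches the `E831`
  group (prefix match on normalised, dot-free codes);
* `venesection_episodes` — the number of *episodes* containing at least one
  X36.2 procedure code. A code repeated within one episode counts once;
  venesection day cases generate one episode each, so this approximates the
  number of treatments;
* `has_g1_code` / `has_g2_code` — any diagnosis position of any episode
  matches the G1 / G2 exclusion group.

Classification is `has_e831 AND venesection_episodes ≥ k AND no excluded
flag`. Thresholds are inclusive ("five or more"). Exclusion is
patient-level: a single G1/G2 code anywhere in the window removes the
patient, which is what makes the rule ladder nested (2 ⊇ 3 ⊇ 4 ⊇ 5 ⊇ 6 as
positive sets, and rule 0 contains everything).

Code matching is prefix matching on normalised codes, so a three-character
ICD-10 category (D56) captures its four-character children. We also let a
four-character prefix capture hypothetical longer children — consistent
with how admitted-patient-care extracts store codes, and a no-op for the
shipped groups.

The baseline cohort keeps patients with at least one in-window episode
carrying E83.1 at age ≥ 18 (age at that admission); all their in-window
episodes are retained for feature building. The study window is the closed
interval 2018-04-01 .. 2023-03-31. Age for the <60/≥60 association test is
age at the first in-window episode; the reference date is otherwise
uncommitted in the source material, and this choice only has to preserve
the direction and strength of the association.

## Accuracy evaluation

Against the chart-review gold standard (positive class: C282Y
homozygosity; compound heterozygotes and everything else are negatives) a
rule yields a 2×2 table, from which sensitivity, specificity, PPV and NPV
are computed with exact Clopper–Pearson 95% intervals (beta-quantile closed
form of inverting the binomial tails). The exact method was selected
because it reproduces every published interval bound at 1 dp while the
Wilson score interval fails several (e.g. 416/479 upper bound: exact 89.7
vs Wilson 89.6); the test suite pins this discrimination. Percentages are
rendered half-up at 1 dp; internal values keep full precision. A metric
with zero denominator is reported as missing, never as 0 or 100. The age
association uses the Pearson χ² test without continuity correction (df=1);
only the p < 0.01 bound is asserted, since no exact statistic is published.

## Synthetic cohort: what is fixed, what is derived, what is random

The generator emulates the published validation cohort: 787 adult E83.1
patients, 9264 episodes over five years, with the published joint
distribution of chart-review category × venesection exposure (479 C282Y
homozygotes, 416 venesected; 107 compound heterozygotes, 81 venesected;
... 51 incorrectly coded, 6 venesected). Counts, not the published
percentages (which contain internal rounding inconsistencies), are
authoritative.

**Derived structure.** The validation study does not print how treated
patients distribute over the 1–4 / 5–9 / ≥10 venesection-episode strata,
nor which patients carry exclusion codes. Both are recovered by *integer
inversion* of the published accuracy percentages against the class totals
479/308: for each rule, the unique integer (tp, tn) pair whose 2×2 table
reproduces all four published metrics at 1 dp is found by local search
(`derive_strata`; an inconsistent table is a hard error). Differences
between successive rules then pin the structure down exactly:

* tp: 473, 416, 413, 411, 366, 258 and tn: 34, 143, 155, 166, 172, 219 for
  rules 1–6;
* 6 homozygotes carry exclusion codes: 3 venesected with a G1 code
  (co-coded as polycythaemia), 2 venesected with a G2 code (concurrent
  leukaemia), and 1 non-venesected carrier assigned a G2 code — the sixth
  carrier is not individually accounted for in the published narrative and
  is an explicit blueprint assumption;
* 34 non-homozygotes carry exclusion codes: 12 venesected G1 carriers, 11
  venesected G2 carriers, 11 non-venesected (all transfusion-overload, G2).
  The split across gold categories follows the published false-positive
  breakdown of rule 4 (78 compound heterozygotes, 30 other-HH-gene, 20
  hyperferritinaemia, 6 incorrect coding, 8 G1-category patients remain
  false positive); the residual assignment (1 compound heterozygote + 2
  hyperferritinaemia to G1; 2 + 2 + 1 C282Y/x to G2) is fixed in the
  blueprint. Note the published breakdown forces exactly one
  other-HH-gene patient to carry an exclusion code (31 are venesected, 30
  remain false positive);
* venesection strata among eligible (carrier-free) venesected patients:
  homozygotes 45 / 108 / 258, non-homozygotes 6 / 47 / 89.

All of these are validated at blueprint construction, together with
nesting monotonicity and the episode-budget floor; violations raise
`InfeasibleBlueprintError` naming the constraint.

**Random nuisance.** Within a stratum, venesection counts are uniform on
1–4 and 5–9, and 10 plus a geometric tail (p = 0.3, capped 15 above the
floor) for ≥10; excluded carriers draw uniform 1–4 (their counts never
enter a metric). Which concrete code within a group is planted (e.g. D45
vs D75.1, or a random four-character child of a three-character category)
is drawn per patient — group membership, not identity, drives every
result. Patient ids, admission dates (uniform over the window), sexes
(exactly 460 male of 787) and ages are random per seed. Episode volume is
exact: one index episode per patient (carrying E83.1 plus any planted
exclusion code), one episode per venesection (E83.1 + X36.2), and filler
admissions with innocuous distractor diagnoses distributed multinomially
to land on 9264 total; oversized geometric tails are trimmed toward the
stratum floor in the (astronomically unlikely) event the draws exceed the
budget.

**Age model.** Homozygotes draw age ~ N(59, 13²) and all others
~ N(69, 13²), clipped to [18, 100]. These two means and the shared SD were
chosen once so that the pooled median is ≈ 63 with IQR ≈ 53–74 and the
<60/≥60 × homozygosity χ² rejects far below 0.01 at n = 787, matching the
published demographics; they are ordinary blueprint fields.

**Determinism.** The same (blueprint, seed) is bit-identical, down to the
written CSV bytes; different seeds change only nuisance attributes, never
a contingency table. Optional "distractor" patients without E83.1 (plus
one under-age E83.1 carrier) can be appended to exercise baseline
selection; they carry no gold labels and must vanish before evaluation.

## What the synthetic data does and does not show

Passing the closure tests demonstrates that the *pipeline arithmetic* —
code normalisation, episode-level venesection counting, patient-level
exclusion, 2×2 construction, exact intervals, rounding — reproduces the
published results when fed a cohort with the published structure. It says
nothing about how the rules transfer to other hospitals: the generator
does not model real coding noise (positional conventions, transfers,
re-admission structure), outpatient venesection, blood-donor maintenance
therapy, or tertiary-centre case mix, all of which the source study flags
as limitations of the rules themselves.

## Numerical choices and edge cases

* Half-up decimal rounding at 1 dp for display (0.05 → 0.1), full
  precision internally.
* CI bounds at the boundary: lower = 0 when successes = 0, upper = 1 when
  successes = trials; zero trials is an error, not a value.
* Duplicate (patient, episode) rows are dropped with one logged warning;
  an empty baseline selection warns rather than errors.
* Ties in first-episode dating break on episode id, making aggregation
  order-invariant.
* Problem sizes in tests are the study's own (787 patients, 9264
  episodes); the whole suite runs in seconds.
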