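# Methods

## Problem and model

`monotriage` implements a reflex-testing strategy for the laboratory
workup of monocytosis (monocytes ≥ 1 × 10⁹/L and ≥ 10% of WBC, the WHO
screening criterion for chronic myelomonocytic leukemia, CMML). Three
readouts are combined:

* **Smear dysplasia score** — one point per blood-cell lineage
  (neutrophil, erythrocyte, megakaryocytic, monocyte) with ≥ 10%
  dysplastic cells on a 200-cell review; abnormal at score ≥ 1.
* **Monoscore** — a 0–1 analyzer-derived dysplasia score treated here as
  an input value; abnormal at ≥ 0.161 (inclusive; one narrative passage
  elsewhere writes “> 0.161”, but the methods-level definition is “≥”
  and that is what the package implements).
* **Classical monocyte fraction (cMo)** — flow-cytometric monocyte
  partitioning into classical (CD14⁺⁺CD16⁻), intermediate
  (CD14⁺⁺CD16⁺) and nonclassical (CD14^low/neg CD16⁺⁺) subsets; the
  CMML signature is cMo ≥ 94%.

The hierarchical workflow routes each sample as follows. If any CBC
abnormality besides the monocytosis independently mandates a smear
(analyzer flag, platelets < 100 × 10⁹/L, immature granulocytes ≥ 10%,
or a free-text criterion), the smear is read first: dysplasia score ≥ 1
flags CMML; otherwise a negative Monoscore ends the workup and a
positive one reflexes to flow cytometry. Samples with isolated
monocytosis skip the smear: Monoscore negative ends the workup,
positive reflexes to flow. At the flow step cMo ≥ 94% flags CMML; a
“bulbous” inflammatory pattern triggers a recommendation to repeat flow
months later, and the suspicion is upheld only if the record carries a
follow-up confirmation. This avoids asserting clairvoyance while still
letting cohort-level accounting count follow-up-confirmed bulbous CMML
as detected.

## The bulbous pattern

CMML-associated inflammation raises intermediate monocytes and nearly
abolishes nonclassical ones, which can push the classical fraction back
under 94% and mask the signature. The pattern is described but never
quantified in the source literature, so the detector is a package
convention: nonclassical ≤ 3% (healthy mean 10 ± 2%, read as “near
disappearance” ≈ mean − 3 SD) **and** intermediate ≥ 9% (healthy
5 ± 2%, “increase” ≈ mean + 2 SD) **and** cMo below the 94% cutoff
(a cMo-positive sample is called positive, not bulbous). All three
thresholds are configurable in `ScoreConfig`.

## Confidence intervals and rounding

Predictive values and sensitivities are binomial proportions with the
normal-approximation (Wald) 95% CI, z fixed at 1.96, bounds clipped to
[0, 100], displayed after half-up rounding to integer percent. Wald was
chosen because back-calculating the combined-rule tables reproduces the
published bounds (e.g. 60/133 → PPV 45%, CI 37–54; 57/58 → NPV 98%,
CI 95–100; 0-width intervals print as 100–100) where Wilson or exact
intervals do not. Two published bounds (the morphology PPV upper bound
and the Monoscore-or-cMo PPV lower bound) differ by one percentage
point from exact Wald back-calculation under any single rounding
convention; they are noted as irreproducible and not asserted.

## The deterministic 196-patient reference cohort

No patient-level data accompany the study, so `paper_fixture()`
reconstructs a cohort whose joint
(trigger × Monoscore × dysplasia × cMo × diagnosis) distribution matches
every printed count. The trigger arm (72 patients) is copied cell by
cell from the published contingency table. The no-trigger arm (124) is
pinned by the printed arm totals (57 Monoscore-negative including 1
CMML; 67 Monoscore-positive including 22 CMML, of whom 20 cMo-positive
and 2 bulbous with follow-up confirmation; morphology positive in 17/23
CMML and 11/101 nonclonal). The remaining nonclonal cells are not
printed individually; they are solved against the whole-cohort
combined-rule row totals, which force

* 5 of the 11 dysplasia-positive no-trigger nonclonal records to be
  Monoscore-negative (Monoscore-or-dysplasia row total 73),
* 8 Monoscore-negative no-trigger nonclonal records to be cMo-positive
  (Monoscore-or-cMo row total 79),
* 2 dysplasia-positive no-trigger nonclonal records to be cMo-positive
  (reproducing the cMo-alone PPV/NPV of 71%/97%).

The resulting cell table (count, class, trigger, Monoscore+,
dysplasia+, cMo ≥ 94, bulbous, follow-up confirmed) is
`monotriage.synthetic.FIXTURE_CELLS`. Two source-internal
inconsistencies are resolved as follows: (1) the single-technique
narrative says three CMML patients lacked an increased cMo fraction,
but the arm-by-arm tables and footnotes identify four bulbous CMML
patients (two per arm); the fixture follows the tables. (2) The
dysplasia-or-cMo row total (60/0 CMML) is consistent only if the two
no-trigger bulbous CMML patients (morphology-negative, cMo < 94 at
presentation) are counted through their confirmed follow-up; the
combined rules therefore use the follow-up-resolved cMo status when a
record carries a confirmation, while the trigger-arm bulbous patient,
for whom no confirmation is recorded, stays in the double-negative
cell. Numeric readouts behind the class labels are fixed representative
values (Monoscore 0.50/0.05; subset profiles 97/2/1, 88/5/7, and
87/11.5/1.5 for bulbous), so editing any cutoff in `ScoreConfig`
visibly perturbs every fixture-derived statistic.

## Parametric cohort simulator

`simulate_cohort` draws class labels first (prevalence 60/196) and all
readouts conditional on class. The any-trigger probability is a direct
per-class parameter (35/136 and 37/60) because the individual flags
co-occur; given a trigger, individual flags fire with their conditional
marginal rates and the analyzer flag backstops records where none fired.
Monoscore uses Beta(1.5, 7) / Beta(8, 0.45) (medians ≈ 0.15 / 0.98), the
cMo fraction Beta(8, 1.2) / Beta(12, 0.7) × 100 (medians ≈ 90 / 97),
dysplasia scores a truncated categorical with medians 0 / 1, and the
bulbous pattern affects 4/60 of CMML. CBC values are lognormal/normal
around the reported class medians with flag-consistent truncation
(platelets < 100 iff the thrombocytopenia flag, IG ≥ 10% iff the
IG flag). The simulator emulates marginal structure only — it does not
model correlations between readouts beyond the class label, age-severity
gradients, or measurement error, so passing recovery tests demonstrate
the estimators, not real-data performance.

## Event-level cytometry simulator and gating

`simulate_events` draws from a three-component isotropic Gaussian
mixture on (CD14, CD16) log-intensity axes, component centers (2.5, 0.5),
(2.5, 2.0), (1.0, 2.0), SD 0.15. The default rectangular gates put every
center more than 3 SD inside its rectangle, so each component lands in
its intended gate with ≥ 99% probability. Gating computes fractions over
assigned events only, requires ≥ 100 assigned events, closes the
composition exactly to 100, and derives the bulbous flag from the gated
fractions. Compensation, doublet exclusion and contaminant gating of
real panels are out of scope.

## CHAID

Classification CHAID with a binary outcome: Pearson chi-square without
continuity correction; bottom-up category merging at α = 0.05;
Bonferroni multiplier equal to the number of ways to partition the
original categories into the final groups (Stirling number of the second
kind, 1 for binary predictors); split at adjusted p ≤ 0.05 subject to
node-size floors (parent ≥ 20, child ≥ 7) and depth ≤ 4; adjusted-p ties
break on the fixed clinical predictor order (trigger, Monoscore,
dysplasia, cMo). The first split can be forced onto the trigger
indicator, encoding the constraint that a smear is always read when
independently mandated. The source does not report its CHAID software,
alphas or node-size limits; these defaults are standard conventions, and
the structure-recovery test asserts tree topology, not parameter
equality.

For structure recovery, `simulate_rule_table` labels independently drawn
binary predictors noiselessly by the triage rule. Marginals matter here:
with exchangeable Monoscore/cMo marginals the two predictors are
symmetric in the no-trigger branch (label = MS ∧ cMo) and the induced
ordering would be a coin flip, while fixture-like marginals make the cMo
split dominate. The defaults P(trigger) = 0.37, P(dysplasia) = 0.40,
P(Monoscore+) = 0.50, P(cMo+) = 0.70 were fixed once by making the
Monoscore split analytically chi-square-dominant (expected ratio ≈ 2.3
over the cMo split), so recovery of the published hierarchy is a
property of the generator, not of a lucky seed.

## Statistical utilities

Group comparison uses two-sided Mann-Whitney (continuous) or Pearson
chi-square (categorical) via scipy; logistic regression and VIF via
statsmodels (Wald CIs on odds ratios; separation detected via divergent
coefficients or solver failure and flagged, never silently accepted);
ROC/AUC via scikit-learn's rank-based implementation, whose midrank tie
handling makes AUC = U/(n₁·n₂), asserted against scipy's Mann-Whitney U
in the tests. The published baseline-characteristics medians and
multivariate odds ratios depend on the unavailable patient-level data
and are deliberately not numeric targets; the corresponding operations
are validated by parameter recovery on simulated cohorts (odds ratios
within 15% relative error at n = 5000, VIF against its closed form,
AUC against the rank identity).

## Design shape

The package is organized as a functional pipeline over frozen dataclass
records, because the workflow itself is a deterministic rule, not a
fitted model; the one genuinely fitted object, the CHAID tree, also
carries a model/results surface (`ChaidModel(...).fit()` →
`ChaidResults` with `summary()`, `predict`, JSON export).

## Problem sizes and determinism

All stochastic tests are seeded. Default problem sizes — 10,000-record
cohorts for calibration checks, 10,000–100,000 events for gating
recovery, n = 1000 for tree recovery, n = 5000 for logistic recovery —
were chosen as desk-scale sizes at which the binomial/asymptotic
tolerances (3 standard errors; 15% relative error) are comfortably
discriminating. The acceptance script's quantities are deterministic
functions of the reference cohort; its `--seed` is recorded for
provenance.

## Known limitations

* The Monoscore's internal formula (neutrophil/monocyte ratio, Ne-WX,
  monocyte count) is out of scope; the score enters as a value.
* The bulbous thresholds and the fixture's unprinted nonclonal cells are
  conventions (documented above), not published facts.
* Real-instrument I/O (FCS files, analyzer exports), marrow/cytogenetic
  confirmation, and slan-based gating are not modeled.
* `apply_exclusions` trusts caller-supplied context flags (sepsis,
  sample age, follow-up); it does not infer them.
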