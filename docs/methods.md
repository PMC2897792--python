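# Methods

## Problem and design

Administrative claims carry no chart-level severity information, so outcome
studies adjust for case mix with claims-based comorbidity measures:
algorithms that turn a patient's ICD-9-CM diagnosis codes into binary
chronic-condition indicators. This package implements three such measures
and the machinery to compare them head-to-head on a fixed cohort, outcome,
and data period:

* **Charlson/Deyo** — the Deyo ICD-9-CM adaptation of the Charlson index,
  17 categories;
* **Charlson/Romano** — the Romano (Dartmouth–Manitoba) adaptation, also 17
  categories but with broader code lists;
* **Elixhauser** — 30 categories ascertained from secondary diagnoses, with
  a DRG-relatedness screen instead of a prior-admission requirement to
  separate comorbidities from complications.

Each measure is used as a block of presence/absence indicators (no weighted
score): every category enters the logistic model as its own column, which
is what makes the measures comparable by model fit and discrimination.

The comparison design holds everything else fixed: one cohort (index
hospitalizations for an acute condition, AMI, or a chronic one, COPD, in
calendar 2002, adults only, discharged within the study year), one outcome
(in-hospital or 1-year all-cause death), one data period (index admission
only, or index plus a 1-year lookback), varying only the measure — and then
varying only the data period within a measure.

## Cohort construction

The index admission is the patient's earliest admission in the study window
whose principal diagnosis prefix-matches the disease family (AMI = 410.x;
COPD = 490.x, 491.x, 492.x, 494.x, 496.x). All ICD-9-CM comparisons use
decimal-free canonical codes with prefix semantics. Exclusions: age < 18
completed years at the index admit date (exactly 18 is retained), and
discharge after the study cutoff; each exclusion increments a per-rule
ledger so cohort attrition is auditable.

Covariates are age in years (entered linearly, untransformed), male,
aborigine (the race covariate of the emulated single-payer setting), and
surgery, defined by membership of the index DRG in a surgical-DRG table.

Outcomes are closed-interval: in-hospital death means the registry death
date lies in [admit, discharge] *or* the claim's discharged-dead flag is
set (when the two disagree a conflict warning is emitted and the admission
counts as a death — either source positively asserts it); 1-year death
means the death date lies within [admit, admit + 365 d]. The 1-year clock
is anchored at admission because that convention is the most common and
makes in-hospital death imply 1-year death for all realistic stays; the
anchor is a `derive_outcomes` parameter for sensitivity analyses.

Same-day qualifying admissions are tie-broken deterministically (longer
stay, then lexicographically smallest principal code).

## Comorbidity mapping rules

Eligible evidence depends on the data period. `index_only`: the index
admission's secondary diagnoses (at most 4 in this claims format).
`index_plus_prior`: additionally the principal and secondary diagnoses of
every admission with admit date in [index − 365 d, index). The index
principal diagnosis never contributes — it defines the cohort condition.

A category is flagged when an eligible code prefix-matches its list,
subject to two comorbidity-vs-complication rules:

* **Elixhauser DRG screen** — an index-sourced code cannot set a category
  whose screen set contains the index DRG; a prior-sourced code bypasses
  the screen (a condition documented before the stay cannot be its
  complication).
* **Charlson prior-only rule** — optionally, a configurable set of
  categories counts only from prior-sourced codes. The shipped default is
  the empty set, so index-only Charlson models are non-degenerate; a
  documented alternative (`prior_only="complication_prone"`: myocardial
  infarction, congestive heart failure, cerebrovascular disease) makes
  those categories invisible without lookback, the behavior described for
  the original adaptations.

Hierarchy rules run last: a dominant category clears its suppressed partner
(complicated diabetes over uncomplicated; severe over mild liver disease;
metastatic disease over solid tumors). A consequence worth stating: flags
are monotone in the data period *before* hierarchy, but a prior admission
can newly set a dominant category and thereby clear a suppressed flag that
was set under `index_only`, so post-hierarchy monotonicity holds only for
categories no rule suppresses. The property tests assert exactly that.

### Reference tables

The three code lists ship as TSV snapshots authored from the published
ICD-9-CM adaptations (Deyo 1992; Romano 1993; the 30-category Elixhauser
list in its HCUP-style form, with hypertension as a single combined
category). The DRG screen and the surgical-DRG list used with the original
method refer to a proprietary national DRG mapping that is not public, so
the package ships **synthetic stand-ins** (`*_synthetic.tsv`): a compact
DRG universe in which cardiac comorbidity categories are screened against
cardiac DRGs, the pulmonary category against pulmonary DRGs, and vascular
against vascular. Every table is overridable through `load_method` /
`load_surgical_drgs`, so real tables can be dropped in without code
changes.

## Statistical evaluation

Models are plain maximum-likelihood logistic regressions (Newton–Raphson,
gradient tolerance 1e-8; a quasi-Newton fallback supplies coefficients when
the Hessian is singular or separation aborts the Newton step, and the
result carries a separation flag). Comorbidity columns with 0% or 100%
prevalence in the analytic cohort are dropped before fitting and their
names recorded.

* **G²** = 2(ℓ_full − ℓ_base) for the nested baseline-vs-full pair,
  chi-squared with df equal to the parameter-count difference. Because
  published tables sometimes print the *total* non-intercept parameter
  count of the full model instead, both `df_diff` (used for the p-value)
  and `df_total` are reported. Negative G² beyond a 1e-6 tolerance is
  treated as a fitting failure, not clipped silently.
* **c-statistic** — concordance probability with ties counted one-half,
  computed from midranks (exact, O(n log n)); equal to the Mann–Whitney
  U-based estimator, which the tests verify independently, along with
  brute-force pair enumeration on small fixtures.
* **Bootstrap** — percentile CIs (2.5th/97.5th) from resampling patients
  with replacement to the original n, *refitting the model inside every
  replicate* and scoring the replicate's own rows; 1000 replicates by
  default. Refitting is the default because it propagates model-fitting
  variability; `refit=False` rescoring is available. Replicates with a
  single-class outcome are redrawn and counted; more than 10% redraws
  triggers a warning. Paired comparisons refit both models on the same
  resampled rows and report the fraction of replicates each wins, with
  exact ties reported separately.

One caveat the null tests document: with in-replicate refitting and
in-sample scoring, a model that nests another plus a pure-noise column
acquires a hair-thin systematic overfitting edge (mean c difference on the
order of 5e-4). Win fractions for *nested* pairs therefore shouldn't be
read as symmetric-null probabilities; between non-nested models of equal
quality the win fraction is centred as expected.

## Synthetic data generator

The generator emulates the schema and statistical structure of an
inpatient claims extract linked to a death registry, because the real data
the design targets are not public. Per patient: demographics from
configured marginals; independent Bernoulli latent comorbidities;
an index admission in 2002 (principal diagnosis from the disease family,
DRG surgical iff the patient is a surgery case); Poisson prior admissions
in the lookback year; and death from a logistic model over latent flags and
baseline covariates. Two intercepts (in-hospital, 1-year) share one
coefficient vector; a single uniform draw per patient decides both
outcomes, so in-hospital death implies 1-year death and mortality is
monotone in every coefficient under common random numbers. The age
coefficient is log-odds per year applied to (age − 70); with the 1-year
intercept above the in-hospital one, both outcomes are exactly marginally
logistic, which is what makes parameter recovery a clean test.

Coding realism is deliberately minimal and controlled by one dial,
`carryover_prob`: each latent condition is coded on any given admission
(index or prior) with that probability, at most 4 secondary slots per
claim. This single mechanism is what makes the lookback period
informative — a condition missed at index may surface on a prior claim.
The generator does *not* simulate hospital-level coding-depth differences,
correlated comorbidities, DRG grouping logic, transfers, or readmission
dependence; passing tests therefore demonstrate the pipeline's correctness
and the direction of period/measure effects under these idealized
conditions, not performance magnitudes on real claims.

### Shipped scenarios

Three YAML scenarios ship as package data; their demographic marginals and
marginal mortality rates are calibrated to the published characteristics of
the populations they emulate, and the intercepts were solved once by
root-finding the marginal-rate equation (`calibrate_intercept`):

* `ami` — n = 20,000, age 66.31 ± 13.36, 72.06% male, 1.8% aborigine,
  14.5% surgery; in-hospital mortality 14.94%, 1-year 27.07%.
* `copd` — n = 20,000, age 72.54 ± 12.10, 72.2% male, 4.12% aborigine,
  1.17% surgery; in-hospital 3.02%, 1-year 22.48%.
* `dominance` — n = 5,000, AMI-like; mortality loads partly on categories
  only the Elixhauser measure observes (arrhythmia, fluid/electrolyte
  disorders, coagulopathy, weight loss, depression) and on codes the
  Romano lists capture but the Deyo lists miss (hypertensive CHF 402.91,
  dementia 294.1, liver 571.9, PVD 440.x), so the expected discrimination
  order is Elixhauser > Charlson/Romano > Charlson/Deyo in every stratum,
  with `carryover_prob = 0.6` making lookback valuable to the Charlson
  variants.

Comorbidity prevalences are stated assumptions of the scenarios (the
emulated study reports none); they are chosen at values typical of elderly
inpatient cohorts. No published model-fit number is claimed to be
reproduced — orderings on the dominance scenario are scenario properties.

## Problem sizes used by the shipped tests and analyses

Parameter recovery runs 20 seeded draws of the `ami` scenario at
n = 20,000 and checks pooled 95% Wald coverage of all generating
coefficients (≥ 90%; per-run joint coverage of ~15 intervals would be
~0.46 even for a perfect implementation). The rank-order check runs the
dominance scenario at n = 5,000 with 200 bootstrap replicates. The
bootstrap-coverage study uses 40 datasets of n = 500 with 100 replicates
against a large-sample truth estimated once at n = 100,000, with an
85–100% acceptance band matching that Monte Carlo size. The numbered
analysis drivers default to the scenario sizes and accept `--n-patients` /
`--n-bootstrap` overrides.

## Known limitations

* Latent comorbidities are independent; real comorbidity co-occurrence
  would change measured prevalences after hierarchy rules and the relative
  value of broader code lists.
* The DRG screen and surgical table are synthetic stand-ins; absolute flag
  prevalences under screening are not comparable to published ones.
* The bundled code lists are snapshots; users validating against a
  specific HCUP release should override the tables.
* Plain logistic regression is kept deliberately (no penalization by
  default); rare categories in small cohorts can separate, which is
  flagged but not corrected.
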