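# comorbidikit

Claims-based comorbidity measures and their head-to-head evaluation.

Outcome studies on administrative data must adjust for case mix using only
coded diagnoses. This package implements the three standard ICD-9-CM
comorbidity measures — **Charlson/Deyo** (17 categories),
**Charlson/Romano** (17 categories, broader code lists), and **Elixhauser**
(30 categories with a DRG-relatedness screen) — as binary-category mappers
over inpatient claims, plus everything needed to compare them on a fixed
cohort: index-hospitalization cohort construction, two data periods (index
admission only vs. index + 1-year lookback), in-hospital and 1-year
mortality outcomes, logistic risk-adjustment models, G² nested-model
statistics, and bootstrap c-statistic comparison. A synthetic claims
generator with a known logistic mortality model makes the whole pipeline
testable end to end, including parameter recovery against ground truth.

It is written for health-services and epidemiology researchers who work
with inpatient claims and want auditable, configurable implementations of
these measures rather than one-off SAS/SQL scripts.

## The statistics at the core

For a cohort of n patients with binary outcome y (death), each model is a
logistic regression

    logit P(y=1) = β₀ + β_age·age + β_male·male + β_abo·aborigine
                   + β_surg·surgery + Σ_k γ_k C_k

where C_k are one measure's comorbidity indicators (0%/100%-prevalence
columns dropped). Model fit gain over the nested baseline is

    G² = 2·(ℓ_full − ℓ_base)  ~  χ²(df = #parameters added).

Discrimination is the c-statistic (ROC area): the probability a random
death outranks a random survivor, ties counted ½, with a percentile
bootstrap 95% CI (resample patients with replacement, refit, rescore;
1000 replicates by default). Paired comparisons refit two measures on the
same bootstrap replicate and count wins.

## Worked example

The numbered scripts under `analysis/` run the full comparison on the two
shipped synthetic populations (an AMI-like acute cohort and a COPD-like
chronic cohort):

```sh
python analysis/01_simulate.py --seed 2002 --n-patients 9000
python analysis/02_build_cohorts.py
python analysis/03_map_comorbidities.py
python analysis/04_evaluate_models.py --seed 2002 --n-bootstrap 100
python analysis/05_report.py
```

Step 01 prints the realized marginals against the scenario targets:

```
[ami] n=9000, 22466 admissions
  age mean 66.33 (target 66.31); in-hospital mortality 14.43% (target 14.94); 1-year 26.96% (target 27.07)
```

Step 04 prints the discrimination ranking per stratum, e.g. for the
AMI-like cohort:

```
  one_year     index_only        elixhauser (0.695) > charlson_romano (0.694) > charlson_deyo (0.691)
  one_year     index_plus_prior  elixhauser (0.706) > charlson_romano (0.701) > charlson_deyo (0.698)
```

and step 05 checks the three qualitative findings the design probes:

```
  one_year: all measures beat baseline (c=0.671): True
    index_only: Elixhauser > Romano > Deyo: True
    index_plus_prior: Elixhauser > Romano > Deyo: True
  charlson_deyo 1-year lookback gain in c: +0.0068
```

Read: every comorbidity measure improves on the demographics-only baseline;
the Elixhauser measure discriminates best (it observes categories the
Charlson lists lack, and Romano's broader lists beat Deyo's), and the
Charlson measures gain from the 1-year lookback because a condition missed
on the index claim can surface on a prior one. On these synthetic cohorts
the c values themselves are scenario properties — only the orderings are
meaningful.

The same pipeline runs behind one command on any run-config YAML
(`comorbidikit run-all --config scenario.yaml --seed 42 --out results/`)
or on real claims files via `admissions_path`/`patients_path` (CSV schema
in `comorbidikit/io.py`). All reference tables — code lists, the DRG
screen, the surgical-DRG list — are overridable; the shipped DRG tables
are synthetic stand-ins (see `docs/methods.md`).

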