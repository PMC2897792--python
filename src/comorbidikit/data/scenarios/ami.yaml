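n_patients: 20000
disease: AMI
age_mean_sd:
- 66.31
- 13.36
male_frac: 0.7206
aborigine_frac: 0.018
surgery_frac: 0.145
prior_admission_rate: 1.5
carryover_prob: 0.6
seed: 20020101
comorbidity_prevalences:
  chf: 0.22
  dementia: 0.08
  arrhythmia: 0.18
  fluid_electrolyte: 0.12
  coagulopathy: 0.04
  weight_loss: 0.05
  depression: 0.08
  renal: 0.1
  diabetes: 0.25
  diabetes_complicated: 0.06
  mild_liver: 0.05
  chronic_pulmonary: 0.15
  malignancy: 0.06
  metastasis: 0.02
  pvd: 0.06
  hypertension: 0.45
mortality_coefficients:
  age: 0.05
  male: 0.1
  aborigine: 0.2
  surgery: -0.4
  chf: 0.45
  dementia: 0.5
  arrhythmia: 0.45
  fluid_electrolyte: 0.55
  coagulopathy: 0.6
  weight_loss: 0.65
  depression: 0.25
  renal: 0.5
  diabetes: 0.2
  diabetes_complicated: 0.4
  mild_liver: 0.35
  chronic_pulmonary: 0.3
  malignancy: 0.7
  metastasis: 1.4
  pvd: 0.3
  hypertension: 0.1
comorbidity_codes:
  chf:
  - '4280'
  - '40291'
  dementia:
  - '2900'
  - '2941'
  arrhythmia:
  - '42731'
  - '42789'
  fluid_electrolyte:
  - '2762'
  - '2765'
  coagulopathy:
  - '2866'
  - '2869'
  weight_loss:
  - '2639'
  - '7832'
  depression:
  - '311'
  - '3004'
  renal:
  - '585'
  - '586'
  diabetes:
  - '25000'
  - '25001'
  diabetes_complicated:
  - '25040'
  - '25050'
  mild_liver:
  - '5715'
  - '5719'
  chronic_pulmonary:
  - '4918'
  - '496'
  malignancy:
  - '1629'
  - '1539'
  metastasis:
  - '1970'
  - '1977'
  pvd:
  - '4439'
  - '4400'
  hypertension:
  - '4019'
  - '40210'
mortality_intercepts:
- -2.4976
- -1.6556
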