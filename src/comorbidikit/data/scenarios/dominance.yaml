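n_patients: 5000
disease: AMI
age_mean_sd:
- 66.31
- 13.36
male_frac: 0.7206
aborigine_frac: 0.018
surgery_frac: 0.145
prior_admission_rate: 1.5
carryover_prob: 0.6
seed: 20020103
comorbidity_prevalences:
  chf: 0.25
  dementia: 0.12
  arrhythmia: 0.25
  fluid_electrolyte: 0.2
  coagulopathy: 0.08
  weight_loss: 0.08
  depression: 0.12
  renal: 0.12
  diabetes: 0.22
  diabetes_complicated: 0.06
  mild_liver: 0.06
  chronic_pulmonary: 0.2
  malignancy: 0.07
  metastasis: 0.03
  pvd: 0.08
  hypertension: 0.4
mortality_coefficients:
  age: 0.05
  male: 0.1
  aborigine: 0.2
  surgery: -0.4
  chf: 0.5
  dementia: 0.55
  arrhythmia: 0.6
  fluid_electrolyte: 0.8
  coagulopathy: 0.7
  weight_loss: 0.8
  depression: 0.45
  renal: 0.5
  diabetes: 0.25
  diabetes_complicated: 0.45
  mild_liver: 0.5
  chronic_pulmonary: 0.35
  malignancy: 0.8
  metastasis: 1.4
  pvd: 0.45
  hypertension: 0.2
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
- -3.0234
- -1.979
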