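# Synthetic observed dataset: 12 subjects, 20% residual CV, EM 30 mg tablet.
scenario:
  individual: {ethnicity: Asian, sex: male, age_years: 30}
  activity_score: 1.5
  regimen: {dose_mg: 30.0, formulation: tablet}
  t_end_h: 24.0
n_subjects: 12
residual_cv: 0.2
seed: 42
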