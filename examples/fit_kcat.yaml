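# Monte-Carlo identification of the CYP2D6 turnover against an observed
# profile (e.g. one generated by `codeine-pbpk synth`).
scenario:
  individual: {ethnicity: Asian, sex: male, age_years: 30}
  activity_score: 1.5
  regimen: {dose_mg: 30.0, formulation: tablet}
  t_end_h: 24.0
parameters:
  kcat_2D6: [0.1, 5.0]
n: 2000
seed: 1
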