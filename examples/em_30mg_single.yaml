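# Extensive metaboliser (AS 1.5), single 30 mg codeine tablet, Asian adult.
individual:
  ethnicity: Asian
  sex: male
  age_years: 30
activity_score: 1.5
regimen:
  dose_mg: 30.0
  formulation: tablet
t_end_h: 24.0
seed: 0
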