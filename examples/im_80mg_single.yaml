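# Intermediate metaboliser (AS 0.75), single 80 mg codeine tablet, Asian adult.
individual: {ethnicity: Asian, sex: male, age_years: 30}
activity_score: 0.75
regimen: {dose_mg: 80.0, formulation: tablet}
t_end_h: 24.0
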