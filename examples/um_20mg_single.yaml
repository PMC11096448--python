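# Ultra-rapid metaboliser (AS 2.75), single 20 mg codeine tablet, Asian adult.
individual: {ethnicity: Asian, sex: male, age_years: 30}
activity_score: 2.75
regimen: {dose_mg: 20.0, formulation: tablet}
t_end_h: 24.0
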