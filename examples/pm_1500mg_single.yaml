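# Poor metaboliser (AS 0), single 1500 mg codeine tablet, Asian adult.
# The dose is the model-based equivalence dose; it exceeds the labelled
# daily maximum and triggers a solubility warning (see the methods note).
individual: {ethnicity: Asian, sex: male, age_years: 30}
activity_score: 0.0
regimen: {dose_mg: 1500.0, formulation: tablet}
t_end_h: 24.0
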