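# Reference physiology: typical 30-year-old African-American adult male.
# Anthropometry from US adult survey reference values; enzyme abundances are
# not distinguished between ethnic references (body-size scaling only).
name: african_american_male
sex: male
age_years: 30
ethnicity: AfricanAmerican
body_weight_kg: 80.0
height_cm: 178.0
cardiac_output_L_min: 6.96   # 6.5 * (80/73)**0.75
gfr_mL_min: 128.5
hematocrit: 0.45
volume_scale: 1.096          # 80/73
enzyme_abundance:
  CYP2D6: 1.0
  CYP3A4: 1.0
  UGT2B7: 1.0
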