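# Reference physiology: typical 30-year-old European adult male.
# Anthropometry from standard adult reference-man tables; organ volumes are
# the canonical organ table (organ_table.yaml) times volume_scale.
name: european_male
sex: male
age_years: 30
ethnicity: European
body_weight_kg: 73.0
height_cm: 176.0
cardiac_output_L_min: 6.5
gfr_mL_min: 120.0
hematocrit: 0.45
volume_scale: 1.0
enzyme_abundance:        # relative to reference liver content (1.0 = reference)
  CYP2D6: 1.0
  CYP3A4: 1.0
  UGT2B7: 1.0
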