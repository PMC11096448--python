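# Reference physiology: typical 30-year-old Asian adult male.
# Body size from East-Asian adult reference anthropometry (~60 kg, 170 cm);
# organ volumes scale isometrically with body weight, cardiac output and GFR
# allometrically (exponent 0.75). Enzyme abundances equal the European
# reference: only anthropometric scaling differs between ethnic references.
name: asian_male
sex: male
age_years: 30
ethnicity: Asian
body_weight_kg: 60.0
height_cm: 170.0
cardiac_output_L_min: 5.61   # 6.5 * (60/73)**0.75
gfr_mL_min: 103.6            # 120 * (60/73)**0.75
hematocrit: 0.45
volume_scale: 0.822          # 60/73
enzyme_abundance:
  CYP2D6: 1.0
  CYP3A4: 1.0
  UGT2B7: 1.0
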