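# Morphine compound file. Morphine carries both an acidic (phenol, 8.21) and
# a basic (tertiary amine, 7.93) pKa and is treated as an ampholyte in the
# partitioning model. Formed in the liver from codeine via CYP2D6 (1:1
# molar); glucuronidation (UGT2B7) is the only modelled elimination pathway
# besides renal clearance, with the platform-style specific clearance as the
# hepatic intrinsic-clearance anchor.
name: morphine
molecular_weight: 285.34
logP: 0.77
pKa_acid: 8.21
pKa_base: 7.93
ionization_class: ampholyte
solubility_mg_per_mL_pH7: 10.2
fraction_unbound_plasma: 0.654
blood_to_plasma_ratio: 1.34
renal_clearance_mL_min_kg: 6.5
specific_clearance_per_min: 5.14
pathways:
  - enzyme: UGT2B7
    kinetic_mode: vmax_based
    km_uM: 212.0                # 0.212 mM
    vmax_pmol_min_mg: 650.0
    product: sink               # M3G/M6G, not tracked
formulations: {}
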