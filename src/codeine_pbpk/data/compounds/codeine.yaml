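# Codeine compound file: physicochemistry, binding, clearance and oral
# formulation parameters. Km values are stored in uM.
#
# specific_clearance_per_min is the platform-style total hepatic intrinsic
# clearance anchor (first-order on unbound liver concentration, per litre of
# liver); the model decomposes it across the listed enzyme pathways in
# proportion to their kinetic ratios (kcat/Km, Vmax/Km).
# total_hepatic_clearance_mL_min_kg is the literature plasma-clearance input
# from which that value derives; it is metadata and not applied as an
# additional elimination process.
name: codeine
molecular_weight: 299.36        # g/mol
logP: 2.6
pKa_acid: 13.78
pKa_base: 9.19
ionization_class: base
solubility_mg_per_mL_pH7: 0.577
fraction_unbound_plasma: 0.925
blood_to_plasma_ratio: 0.97
renal_clearance_mL_min_kg: 5.0
total_hepatic_clearance_mL_min_kg: 20.32
specific_clearance_per_min: 1.88
pathways:
  - enzyme: CYP2D6
    kinetic_mode: kcat_based
    km_uM: 100.0
    kcat_per_min: 1.6           # extensive-metabolizer reference (AS = 1.5)
    product: morphine
  - enzyme: CYP3A4
    kinetic_mode: kcat_based
    km_uM: 104.1
    kcat_per_min: 2.8
    product: sink               # demethylcodeine, not tracked further
  - enzyme: UGT2B7
    kinetic_mode: vmax_based
    km_uM: 2320.0               # 2.32 mM
    vmax_pmol_min_mg: 573.0
    product: sink               # codeine-6-glucuronide
formulations:
  capsule:   {dissolution_t50_min: 5.0,   dissolution_shape: 1.0}
  tablet:    {dissolution_t50_min: 5.0,   dissolution_shape: 0.92}
  sr_tablet: {dissolution_t50_min: 100.0, dissolution_shape: 1.2}
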