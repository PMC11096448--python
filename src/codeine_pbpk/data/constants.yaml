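# Model constants: permeability correlation, oral transit chain, solver
# tolerances and enzyme reference scales.

# Cellular permeability correlation (cm/min):
#   log10 P = c0 + c1 * logP - c2 * log10(MW)
# The package's own lipophilicity/size correlation, anchored so that a
# lipophilic opiate (logP 2.6, MW ~300) falls in the high-permeability class
# (~8e-4 cm/s) and a hydrophilic one (logP 0.77) in the moderate class
# (~1e-4 cm/s), consistent with Caco-2/PAMPA ranges for these drug classes.
permeability:
  c0: 2.41
  c1: 0.47
  c2: 2.0

# Oral absorption: first-order gastric emptying into a serial small-intestine
# transit chain; absorption from each segment at ka = 2 * P_cell / r.
gut:
  gastric_emptying_half_time_min: 15.0
  n_segments: 6
  small_intestine_transit_h: 3.3
  effective_radius_cm: 1.25

solver:
  rtol: 1.0e-8
  atol: 1.0e-10       # internal amounts in umol
  rtol_fast: 1.0e-6   # used by Monte-Carlo fitting loops
  atol_fast: 1.0e-8

# Reference enzyme scale factors multiplying the pathway capacity derived
# from the specific-clearance decomposition. The CYP2D6 scale is calibrated
# once so that the Asian extensive-metabolizer reference (AS = 1.5) after a
# single 30 mg codeine tablet reproduces the reference morphine exposure
# (AUC_0-inf 9.07 ng.h/mL), then frozen here. See codeine_pbpk.calibration.
enzyme_scales:
  CYP2D6: 2.433042    # frozen result of calibrate_cyp2d6_scale()
  CYP3A4: 1.0
  UGT2B7: 1.0

# Morphine exposure reference used by the one-time CYP2D6 scale calibration
# and by phenotype dose matching (Asian EM, 30 mg single oral tablet).
em_reference:
  dose_mg: 30.0
  formulation: tablet
  auc_ng_h_ml: 9.07
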