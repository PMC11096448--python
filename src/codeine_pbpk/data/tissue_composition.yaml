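# Tissue composition inputs for tissue:plasma partitioning.
#
# Per tissue: fractional extracellular water (f_ew), intracellular water
# (f_iw), neutral lipid (f_nl), neutral phospholipid (f_np) (all v/v),
# acidic phospholipid content AP (mg/g tissue), tissue:plasma albumin ratio
# and intracellular pH. Values compiled from the standard published
# rat/human tissue-composition tables used with the Rodgers-Rowland
# partitioning method; gonads/stomach/rest use gut-like generic values.
#
# blood_cells and plasma entries supply the reference phases: blood-cell
# composition is used to back out the acidic-phospholipid association
# constant from the measured blood:plasma ratio.
pH_plasma: 7.4
pH_intracellular: 7.0
pH_blood_cells: 7.22
tissues:
  adipose:  {f_ew: 0.135, f_iw: 0.017, f_nl: 0.790,  f_np: 0.0020, ap_mg_g: 0.40, albumin_ratio: 0.049, pH_iw: 7.0}
  bone:     {f_ew: 0.100, f_iw: 0.346, f_nl: 0.074,  f_np: 0.0011, ap_mg_g: 0.67, albumin_ratio: 0.100, pH_iw: 7.0}
  brain:    {f_ew: 0.162, f_iw: 0.620, f_nl: 0.051,  f_np: 0.0565, ap_mg_g: 0.40, albumin_ratio: 0.048, pH_iw: 7.0}
  gut:      {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0487, f_np: 0.0163, ap_mg_g: 2.41, albumin_ratio: 0.158, pH_iw: 7.0}
  heart:    {f_ew: 0.320, f_iw: 0.456, f_nl: 0.0115, f_np: 0.0166, ap_mg_g: 2.25, albumin_ratio: 0.157, pH_iw: 7.0}
  kidney:   {f_ew: 0.273, f_iw: 0.483, f_nl: 0.0207, f_np: 0.0162, ap_mg_g: 5.03, albumin_ratio: 0.130, pH_iw: 7.0}
  liver:    {f_ew: 0.161, f_iw: 0.573, f_nl: 0.0348, f_np: 0.0252, ap_mg_g: 4.56, albumin_ratio: 0.086, pH_iw: 7.0}
  lung:     {f_ew: 0.336, f_iw: 0.446, f_nl: 0.0030, f_np: 0.0090, ap_mg_g: 3.91, albumin_ratio: 0.212, pH_iw: 7.0}
  muscle:   {f_ew: 0.118, f_iw: 0.630, f_nl: 0.0238, f_np: 0.0072, ap_mg_g: 1.53, albumin_ratio: 0.064, pH_iw: 7.0}
  skin:     {f_ew: 0.382, f_iw: 0.291, f_nl: 0.0284, f_np: 0.0111, ap_mg_g: 1.32, albumin_ratio: 0.277, pH_iw: 7.0}
  spleen:   {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0201, f_np: 0.0198, ap_mg_g: 3.18, albumin_ratio: 0.097, pH_iw: 7.0}
  pancreas: {f_ew: 0.120, f_iw: 0.664, f_nl: 0.0403, f_np: 0.0090, ap_mg_g: 0.40, albumin_ratio: 0.060, pH_iw: 7.0}
  stomach:  {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0487, f_np: 0.0163, ap_mg_g: 2.41, albumin_ratio: 0.158, pH_iw: 7.0}
  gonads:   {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0200, f_np: 0.0100, ap_mg_g: 2.00, albumin_ratio: 0.150, pH_iw: 7.0}
  rest:     {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0200, f_np: 0.0100, ap_mg_g: 2.00, albumin_ratio: 0.150, pH_iw: 7.0}
blood_cells: {f_ew: 0.0, f_iw: 0.603, f_nl: 0.0017, f_np: 0.0029, ap_mg_g: 0.50, albumin_ratio: 0.0, pH_iw: 7.22}
plasma:      {f_water: 0.945, f_nl: 0.0023, f_np: 0.0013}
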