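# Canonical organ table for the whole-body model: 18 compartments.
#
# Volumes are for the 73-kg adult male anchor; per-reference files scale them
# by `volume_scale`. Flow fractions are fractions of cardiac output for the
# systemic circulation (they sum to 1; the lung carries total cardiac output
# and the portal vein collects the splanchnic organs). Values compiled from
# standard adult reference-man physiology tables (ICRP-type compilations and
# the reference tables commonly used in whole-body PBPK software).
#
# portal_drained organs drain into the portal vein, which perfuses the liver
# together with the hepatic artery (flow fraction of the `liver` row below).
organs:
  lung:            {volume_L: 0.50,  flow_fraction: null}   # receives total cardiac output
  liver:           {volume_L: 1.80,  flow_fraction: 0.065}  # hepatic artery only
  kidney:          {volume_L: 0.31,  flow_fraction: 0.190}
  gut:             {volume_L: 1.10,  flow_fraction: 0.145}
  stomach:         {volume_L: 0.15,  flow_fraction: 0.010}
  spleen:          {volume_L: 0.15,  flow_fraction: 0.020}
  pancreas:        {volume_L: 0.10,  flow_fraction: 0.010}
  muscle:          {volume_L: 29.0,  flow_fraction: 0.170}
  adipose:         {volume_L: 14.5,  flow_fraction: 0.050}
  brain:           {volume_L: 1.45,  flow_fraction: 0.120}
  heart:           {volume_L: 0.33,  flow_fraction: 0.040}
  skin:            {volume_L: 3.30,  flow_fraction: 0.058}
  bone:            {volume_L: 10.5,  flow_fraction: 0.050}
  gonads:          {volume_L: 0.035, flow_fraction: 0.003}
  rest:            {volume_L: 3.50,  flow_fraction: 0.069}
  arterial_blood:  {volume_L: 1.70,  flow_fraction: null}
  venous_blood:    {volume_L: 3.90,  flow_fraction: null}
  portal_vein:     {volume_L: 0.10,  flow_fraction: null}   # flow = sum of portal-drained organs
portal_drained: [gut, stomach, spleen, pancreas]
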