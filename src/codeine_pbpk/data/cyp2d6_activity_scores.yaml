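# CYP2D6 activity-score table: turnover frequency (kcat, 1/min) and relative
# turnover (% of the AS=1.5 extensive-metabolizer reference, kcat 1.6/min)
# per modelled activity score. The poor-metabolizer kcat is a small positive
# value (0.03/min), not zero: clinical data show residual morphine formation
# in PMs. Non-tabulated scores in [0, 3] are linearly interpolated.
rows:
  - {activity_score: 0.0,  phenotype: PM, kcat_per_min: 0.03, kcat_rel_percent: 2}
  - {activity_score: 0.5,  phenotype: IM, kcat_per_min: 0.40, kcat_rel_percent: 25}
  - {activity_score: 0.75, phenotype: IM, kcat_per_min: 0.6,  kcat_rel_percent: 37.5}
  - {activity_score: 1.0,  phenotype: IM, kcat_per_min: 0.8,  kcat_rel_percent: 50}
  - {activity_score: 1.25, phenotype: EM, kcat_per_min: 0.96, kcat_rel_percent: 65}
  - {activity_score: 1.5,  phenotype: EM, kcat_per_min: 1.6,  kcat_rel_percent: 100}
  - {activity_score: 1.75, phenotype: EM, kcat_per_min: 1.87, kcat_rel_percent: 117}
  - {activity_score: 2.0,  phenotype: EM, kcat_per_min: 2.16, kcat_rel_percent: 135}
  - {activity_score: 2.5,  phenotype: UM, kcat_per_min: 2.4,  kcat_rel_percent: 150}
  - {activity_score: 3.0,  phenotype: UM, kcat_per_min: 2.8,  kcat_rel_percent: 175}
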