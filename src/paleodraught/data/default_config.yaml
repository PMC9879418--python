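# Default analysis configuration. Every threshold the rule set uses lives
# here; values are the documented defaults of the methods implemented.
index:
  variant: normalised_sum      # or feature_mean
  oa_present_is_high: true     # absent -> 1, present -> 2 (monotone coding)
traction_threshold: 0.75       # e/D1 at or above this is traction-consistent
sex_rules:
  bd_female_max: 63.0          # mm, metacarpal distal breadth
  bd_male_min: 65.0            # mm
  gracility_cow_max: 17.0      # SD/GL x 100
  gracility_bull_range: [17.0, 20.0]
  ox_gl_min: 215.0             # mm; castrate rule, evaluated first
  ox_gracility_range: [15.0, 17.5]
withers_factors:               # GL (mm) x factor / 10 -> withers height (cm)
  metacarpal: {female: 6.03, male: 6.33, castrate_candidate: 6.18}
  metatarsal: {female: 5.33, male: 5.62, castrate_candidate: 5.45}
bootstrap:
  n_boot: 2000                 # limb-bias percentile bootstrap replicates
  level: 0.95
seed: 0
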