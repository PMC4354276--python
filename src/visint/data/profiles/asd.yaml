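# ASD-like observer group profile (see nt.yaml for field meanings).
# The windmill tolerance is synthetic: the shape was only tested on a
# separate neurotypical group, so the lines-level value is used here.
label: ASD
baseline_threshold:
  mean: 0.036
  sd: 0.007
facilitation_db:
  0:  {mean: 3.80, sd: 1.44}
  15: {mean: 2.73, sd: 1.80}
  30: {mean: 1.96, sd: 1.62}
  45: {mean: 1.15, sd: 1.48}
weibull_slope: 3.0
cf_lapse: 0.0
tolerance:
  lines:    {mean: 47.73, sd: 8.28}
  square:   {mean: 51.93, sd: 8.95}
  windmill: {mean: 47.73, sd: 8.28}
tolerance_corr: 0.90
logistic_spread: 8.0
ci_lapse: 0.0
fixation_rate: 0.864
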