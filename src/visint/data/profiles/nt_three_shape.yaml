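# Neurotypical-like profile for the three-shape (lines/windmill/square)
# contour session, modelled on a separate younger control group.
label: NT-3shape
baseline_threshold:
  mean: 0.035
  sd: 0.008
facilitation_db:
  0:  {mean: 4.95, sd: 1.44}
  15: {mean: 3.88, sd: 1.80}
  30: {mean: 3.11, sd: 1.62}
  45: {mean: 2.30, sd: 1.48}
weibull_slope: 3.0
cf_lapse: 0.0
tolerance:
  lines:    {mean: 43.90, sd: 6.18}
  square:   {mean: 56.07, sd: 4.69}
  windmill: {mean: 47.80, sd: 6.28}
tolerance_corr: 0.56
logistic_spread: 8.0
ci_lapse: 0.0
fixation_rate: 0.943
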