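# Neurotypical-like observer group profile.
# Collinear facilitation: baseline contrast threshold and facilitation (dB)
# per flanker orientation offset; contour integration: 75% jitter
# tolerance (deg) per contour shape.  Means/SDs are group-level; the
# simulator draws each participant's parameters from truncated normal laws.
label: NT
baseline_threshold:
  mean: 0.035
  sd: 0.008
facilitation_db:          # per flanker orientation offset (deg -> dB)
  0:  {mean: 4.95, sd: 1.44}
  15: {mean: 3.88, sd: 1.80}
  30: {mean: 3.11, sd: 1.62}
  45: {mean: 2.30, sd: 1.48}
weibull_slope: 3.0
cf_lapse: 0.0
tolerance:                # per contour shape (deg of jitter at 75%)
  lines:    {mean: 47.83, sd: 6.86}
  square:   {mean: 57.38, sd: 6.01}
  windmill: {mean: 47.80, sd: 6.28}
tolerance_corr: 0.56      # between-shape correlation of tolerances
logistic_spread: 8.0
ci_lapse: 0.0
fixation_rate: 0.943      # P(per-trial gaze deviation <= 1.5 deg)
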