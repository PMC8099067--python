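# Monetisation of the growth penalty incurred when moving growing pigs from
# the industry-typical group of 50 to groups of 100+. ADG declines linearly
# with group size (0.65 kg/day minus 0.00048 kg per additional pig).
# days_on_phase and the price-per-kg envelope are calibrated so that the
# central value reproduces the packaged large-groups cost row; they are a
# calibration, not independently sourced market figures.
calibrated_to: large_groups lowered_growth_performance cost row (1.20, 1.60, 2.00)
adg_intercept: 0.65
adg_slope_per_pig: 0.00048
base_group_size: 50
target_group_size: 100
days_on_phase: 83.3
price_per_kg:
  low: 0.60
  central: 0.80
  high: 1.00
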