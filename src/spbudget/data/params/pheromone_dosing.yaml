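# Pheromone diffuser dosing and cost model. Product instructions: one
# diffuser per 25 m2 of pen, effective for up to 6 weeks after opening
# (mounted 1.5 m above the floor -- no monetary consequence). A 25 m2 pen
# at 0.65 m2 per pig holds 38 pigs, the batch served by one diffuser
# lifetime. Diffuser price envelope and installation minutes are calibrated
# so the per-pig components reproduce the packaged pheromones cost rows;
# they are a calibration, not quoted list prices.
calibrated_to: pheromones cost rows (0.31, 0.39, 0.46) and (0.01, 0.03, 0.04)
area_per_diffuser_m2: 25.0
diffuser_life_weeks: 6.0
stocking_density_m2_per_pig: 0.65
pen_area_m2: 25.0
pigs_per_pen: 38
weeks_required: 6.0
wage_per_hour: 9.50
price_per_diffuser:
  low: 11.78
  central: 14.82
  high: 17.48
labour_minutes_per_diffuser:
  low: 2.4
  central: 7.2
  high: 9.6
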