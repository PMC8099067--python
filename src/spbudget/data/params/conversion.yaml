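# Defaults for converting survey answers to GBP per pig produced.
# Structural investments are amortised linearly over ten years.
# batches_per_year reflects a ~115-day growing/finishing cycle;
# pigs_per_sow_per_year is an industry-typical UK figure.
lifetime_years: 10.0
batches_per_year: 3.0
pigs_per_sow_per_year: 25.0
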