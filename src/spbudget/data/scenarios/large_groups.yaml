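# Housing growing/finishing pigs in social groups of 100+ by converting
# existing buildings. All values GBP per pig produced.
id: large_groups
label: Housing pigs in large social groups (100+)
items:
  - name: pen_reorganisation_and_labour
    direction: cost
    source: farmer_survey
    low: 0.02
    mode: 0.61
    high: 1.15
  - name: lowered_growth_performance
    direction: cost
    source: literature
    low: 1.20
    mode: 1.60
    high: 2.00
  - name: reduced_aggression
    direction: benefit
    source: farmer_survey
    low: 0.00
    mode: 0.15
    high: 0.30
  - name: reduced_cleaning_labour
    direction: benefit
    source: literature
    low: 0.00
    mode: 0.01
    high: 0.02
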