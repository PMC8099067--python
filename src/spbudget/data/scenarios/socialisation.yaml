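# Pre-weaning socialisation: pairs of litters mixed from the second week of
# life until weaning. All values GBP per pig produced.
id: socialisation
label: Pre-weaning socialisation of litters
items:
  - name: pen_modification_and_labour
    direction: cost
    source: farmer_survey
    low: 0.00
    mode: 0.08
    high: 0.50
  - name: reduced_aggression
    direction: benefit
    source: farmer_survey
    low: 0.00
    mode: 0.15
    high: 0.30
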