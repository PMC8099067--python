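# Exposing pigs to synthetic maternal pheromones via commercial odour
# diffusers. All values GBP per pig produced.
id: pheromones
label: Synthetic maternal pheromones
items:
  - name: diffuser_purchase
    direction: cost
    source: market
    low: 0.31
    mode: 0.39
    high: 0.46
  - name: diffuser_installation_labour
    direction: cost
    source: market
    low: 0.01
    mode: 0.03
    high: 0.04
  - name: reduced_aggression
    direction: benefit
    source: farmer_survey
    low: 0.00
    mode: 0.15
    high: 0.30
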