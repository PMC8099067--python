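# Farmer willingness-to-pay classes from a prior choice experiment with 82
# UK and Irish pig farmers. Rates are per 1% reduction in aggression
# lesions: installation in GBP per pig place, running in GBP per pig
# produced. Only the welfare-motivated class pays for aggression reduction
# specifically. pigs_per_place_lifetime is backed out so the welfare class
# totals 0.77 GBP per pig produced at a 25% reduction; it is a calibration,
# not an independently stated constant.
calibrated_to: welfare_motivated WTP of 0.77 GBP per pig produced at 25% reduction
pigs_per_place_lifetime: 137.5
classes:
  - class_label: non_regroupers
    share_of_farmers: 0.18
    install_rate: 0.00
    running_rate: 0.00
  - class_label: production_only
    share_of_farmers: 0.32
    install_rate: 0.00
    running_rate: 0.00
  - class_label: welfare_motivated
    share_of_farmers: 0.50
    install_rate: 0.11
    running_rate: 0.03
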