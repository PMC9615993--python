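# Illustrative (synthetic) mean prey body masses in kg for worked examples.
# The field study behind the reference FO tables does not publish its mass
# table, so these round literature-style values are NOT the study's inputs;
# relative-biomass outputs computed from them are demonstrations only.
bharal: 55
livestock: 80
marmot: 6
bird: 1
small_prey: 0.5
musk_deer: 12
himalayan_tahr: 70
himalayan_langur: 15
goral: 30
serow: 90
sambar: 180
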