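prey,snow_leopard,common_leopard
bharal,25,4.17
livestock,25,39.58
bird,2,4.17
small_prey,23,29.17
musk_deer,20,4.17
himalayan_tahr,7,0
himalayan_langur,5,0
goral,0,6.25
serow,0,4.17
sambar,0,12.5
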