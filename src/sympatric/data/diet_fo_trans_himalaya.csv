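prey,snow_leopard,woolly_wolf
bharal,40,59
livestock,53,28
marmot,10,15
bird,6,13
small_prey,6,6
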