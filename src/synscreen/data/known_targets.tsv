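drug	gene	method
cerivastatin	hmg1	HOP
tunicamycin	alg7	MSP/HIP
methotrexate	dfr1	HIP
miconazole	erg11	HIP
rapamycin	tor2	MSP/HIP
cantharidin	glc7	HIP
fenpropimorph	erg24	HIP
latrunculin A	act1	resistance mapping
benomyl	tub1	HIP and mutant mapping
sodium fluoride	ipp1	HIP
hydroxyurea	rnr1	HIP and resistance mapping
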