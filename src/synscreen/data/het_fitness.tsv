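mutant	miconazole	benomyl	rapamycin	fenpropimorph	cantharidin	sodium fluoride	hydroxyurea	methotrexate	cerivastatin	tunicamycin	latrunculin A
erg11	0.82	0.76	0.94	0.54	0.95	1.00	0.92	0.99	0.90	0.99	0.90
tub1	0.72	0.81	0.90	0.42	0.69	0.87	0.78	0.83	0.81	0.82	0.35
tor2	0.53	0.73	0.56	0.68	0.90	0.98	0.85	0.96	0.87	0.89	0.65
erg24	0.55	0.74	0.71	0.73	0.88	0.89	0.83	0.90	0.77	0.87	0.68
glc7	0.52	0.79	0.65	0.50	0.58	0.95	0.83	0.90	0.88	0.83	0.68
ipp1	0.61	0.74	0.72	0.78	0.91	0.71	0.89	0.97	0.99	0.89	0.68
rnr1	0.64	0.92	0.73	0.56	0.93	0.96	0.87	0.94	0.90	0.93	0.68
dfr1	0.55	0.92	0.80	0.68	0.93	1.04	0.87	0.78	0.97	0.91	0.75
hmg1	0.56	1.07	0.80	0.68	0.97	1.05	0.90	1.01	0.75	0.91	0.87
alg7	0.76	1.05	0.81	0.55	0.99	1.05	0.94	1.04	0.96	0.79	0.96
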