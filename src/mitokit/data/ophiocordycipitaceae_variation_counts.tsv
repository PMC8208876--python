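species	n_mitogenomes	aligned_length	n_snps	n_indels
Ophiocordyceps sinensis	3	157606	16	144
Hirsutella thompsonii	3	66635	281	6489
Hirsutella rhossiliensis	2	64858	7	2008
Tolypocladium inflatum	5	25338	30	375
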