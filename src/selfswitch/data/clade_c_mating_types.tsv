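species	section	mating_type
B_capuronii	Bifalcula	Outcrossing
B_complanatum	Bifalcula	Dimorphic
B_implexum	Bifalcula	Outcrossing
B_minutum	Bifalcula	Outcrossing
B_sp_nov_A	Bifalcula	Outcrossing
B_sp_nov_B	Bifalcula	Unknown
B_bicoloratum	Calamaria	Trimorphic
B_cirrhoglossum	Calamaria	Outcrossing
B_elliottii	Calamaria	Outcrossing
B_erectum	Calamaria	Dimorphic
B_hildebrandtii	Calamaria	Outcrossing
B_histrionicum	Calamaria	Outcrossing
B_incurvum	Calamaria	Outcrossing
B_lecouflei	Calamaria	Outcrossing
B_luteobracteatum	Calamaria	Outcrossing
B_malawiense	Calamaria	Outcrossing
B_obtusatum	Calamaria	Dimorphic
B_occultum	Calamaria	Dimorphic
B_pervillei	Calamaria	Outcrossing
B_pusillum	Calamaria	Dimorphic
B_quadrifarium	Calamaria	Dimorphic
B_rubrum	Calamaria	Outcrossing
B_ruginosum	Calamaria	Outcrossing
B_senghasii	Calamaria	Outcrossing
B_trifarium	Calamaria	Outcrossing
B_sp_nov_C	Calamaria	Outcrossing
B_sp_nov_D	Calamaria	Unknown
B_sp_nov_E1	Calamaria	Outcrossing
B_sp_nov_E2	Calamaria	Outcrossing
B_humblotii	Humblotiorchis	Dimorphic
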