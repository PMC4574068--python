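constraint	marginal_lnl	se
none	-15887.6	0.301
all_selfers_clade_c	-16563.5	0.317
all_selfers_calamaria_humblotiorchis	-16400.8	0.308
all_selfers_calamaria	-16371.7	0.348
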