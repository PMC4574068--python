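model	df	lam_o	lam_s	mu_o	mu_s	q_os	q_so	lnl	aic	delta_aic	pct_rejecting
qOS=0	5	0.59	0.85	1.05	6.41e-09	0	0.76	-66.97	143.94	-21.83	100
lamO=0	5	0	1.54	1.32e-05	5.88e-08	2.92	5.82	-63.04	136.09	-13.98	98.5
lamO=lamS	5	0.66	0.66	1.26e-07	0.96	0.35	3.41e-06	-61.89	133.77	-11.67	99.3
full	6	0.72	4.81e-07	5.21e-07	0.14	0.29	0.04	-58.68	129.35	-7.25	
qOS=qSO	5	0.72	1.25e-06	3.68e-06	1.03e-05	0.30	0.30	-58.86	127.73	-5.62	0
qSO=0	5	0.71	4.54e-07	8.25e-07	0.25	0.28	0	-58.80	127.60	-5.49	0
muO=muS	5	0.71	2.15e-07	1.97e-06	1.97e-06	0.27	0.16	-58.75	127.50	-5.39	0
muS=0	5	0.71	4.13e-07	6.50e-07	0	0.27	0.17	-58.75	127.50	-5.39	0
muO=0	5	0.72	4.51e-08	0	0.14	0.29	0.04	-58.68	127.36	-5.25	0
lamS=0	5	0.72	0	1.32e-07	0.13	0.29	0.04	-58.68	127.35	-5.25	0
lamS=0,muO=0	4	0.72	0	0	0.14	0.29	0.04	-58.68	125.35	-3.25	0
lamS=0,muO=0,qSO=0	3	0.71	0	0	0.25	0.28	0	-58.80	123.60	-1.49	0
lamS=0,muO=0,muS=0,qSO=0	2	0.68	0	0	0	0.21	0	-59.05	122.11	0	0
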