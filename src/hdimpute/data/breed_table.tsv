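breed	code	breed_type	n_genotyped	n_families	progeny_per_sire	n_eff_ancestors	train_size	valid_size	error_rate_pct	ld70	r_tv
Abondance	ABO	dairy	209	54	3.69	15	169	40	0.75	0.217	0.146
Brown Swiss	BSW	dairy	99	52	1.90	28	79	20	1.92	0.255	0.074
Holstein	HOL	dairy	788	204	2.30	21	634	154	0.73	0.255	0.078
Montbeliarde	MON	dairy	530	139	3.77	18	424	106	0.51	0.196	0.116
Normande	HOR	dairy	551	138	3.82	23	444	107	0.33	0.233	0.104
Simmental	SIM	dairy	125	55	2.24	39	100	25	2.55	0.209	0.050
Tarentaise	TAR	dairy	185	65	2.77	15					
Aubrac	AUB	beef	254	116	2.17	112	204	50	2.03	0.177	0.028
Bazadaise	BAZ	beef	89	60	1.45	46	72	17	2.07	0.239	0.038
Blonde d'Aquitaine	BLA	beef	327	187	1.74	78	262	65	1.80	0.175	0.038
Charolais	CHA	beef	672	310	2.14	249	539	133	0.68	0.176	0.018
Gasconne	GAS	beef	163	76	2.12	197	131	32	2.26	0.174	0.026
Limousine	LIM	beef	462	235	1.96	185	370	92	1.09	0.164	0.014
Parthenaise	PAR	beef	304	97	3.02	89	245	59	1.88	0.161	0.024
Rouge des Pres	RDP	beef	149	80	1.83	99	119	30	2.39	0.206	0.028
Salers	SAL	beef	246	186	1.31	99	197	49	1.27	0.213	0.024
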