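species	ltsp_west	ltsp_woest	stsp_west	stsp_woest	pseudo_west	pseudo_woest
Al	116	103	49	712	10	360
At	161	30	172	335	42	157
Bd	140	37	218	291	107	205
Cp	54	70	4	31	2	37
Cr	1	8	13	61	1	4
Cs	17	135	1	45	0	9
Gm	273	59	39	169	27	135
Me	76	154	6	69	2	16
Mg	135	324	37	255	11	141
Mt	134	257	68	449	14	226
Os	183	64	204	313	42	165
Pp	73	44	60	64	7	10
Pt	95	185	14	93	2	36
Rc	69	89	2	55	4	31
Sb	107	95	123	349	14	129
Sm	63	73	66	258	8	76
Vv	95	107	15	61	7	30
Zm	166	9	121	52	28	41
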