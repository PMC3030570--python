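species	genome_size_mb	total_fbx	ltsp	stsp	pseudogene
Al	206.7	1350	219	761	370
At	119.7	897	191	507	199
Bd	271.9	998	177	509	312
Cp	331.3	198	124	35	39
Cr	112.3	88	9	74	5
Cs	203.1	207	152	46	9
Gm	973.3	702	332	208	162
Me	416.7	323	230	75	18
Mg	321.7	903	459	292	152
Mt	307.5	1148	391	517	240
Os	372.3	971	247	517	207
Pp	480	258	117	124	17
Pt	417.1	425	280	107	38
Rc	350.6	250	158	57	35
Sb	738.5	817	202	472	143
Sm	212.8	544	136	324	84
Vv	497.5	315	202	76	37
Zm	2061	417	175	173	69
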