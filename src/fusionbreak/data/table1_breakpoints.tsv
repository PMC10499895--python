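patient_id	sex	age	phenotype	sample_type	gene	orientation	position	accession	note
2895	f	30	pre-B	pb	TCF3	TCF3::PBX1	1163	OK334233,OK334275	
2895	f	30	pre-B	pb	PBX1	TCF3::PBX1	40275	OK334233,OK334275	
2895	f	30	pre-B	pb	TCF3	PBX1::TCF3	1297	OK334233,OK334275	
2895	f	30	pre-B	pb	PBX1	PBX1::TCF3	40249	OK334233,OK334275	
3069	m	19	common	bm	TCF3	TCF3::PBX1	1180	ON809522	
3069	m	19	common	bm	PBX1	TCF3::PBX1	140360	ON809522	
3120	m	19	pre-B	bm	TCF3	TCF3::PBX1	1179	OK334234	
3120	m	19	pre-B	bm	PBX1	TCF3::PBX1	127732	OK334234	
3596	m	50	pre-B	bm	TCF3	TCF3::PBX1	1182	OK334235	
3596	m	50	pre-B	bm	PBX1	TCF3::PBX1	121859	OK334235	
3766	m	17	pre-B	pb	TCF3	TCF3::PBX1	1178	OK334236	
3766	m	17	pre-B	pb	PBX1	TCF3::PBX1	228226	OK334236	
3878	f	27	pre-B	bm	TCF3	TCF3::PBX1	1782	OK334237	
3878	f	27	pre-B	bm	PBX1	TCF3::PBX1	221288	OK334237	
3951	f	24	pre-B	bm	TCF3	TCF3::PBX1	2151	OK334238	ambiguous printed cell 215111,457 parsed as TCF3 2151 / PBX1 11457; parse reproduces printed cluster totals
3951	f	24	pre-B	bm	PBX1	TCF3::PBX1	11457	OK334238	ambiguous printed cell 215111,457 parsed as TCF3 2151 / PBX1 11457; parse reproduces printed cluster totals
3999	f	19	pre-B	bm	TCF3	TCF3::PBX1	1180	OK334239	
3999	f	19	pre-B	bm	PBX1	TCF3::PBX1	188792	OK334239	
4167	f	57	pre-B	bm	TCF3	TCF3::PBX1	1183	OK334240	
4167	f	57	pre-B	bm	PBX1	TCF3::PBX1	142143	OK334240	
4297	f	24	pre-B	pb	TCF3	TCF3::PBX1	1179	OK334241,OK334276	junction carries an insertion derived from FGF6 (chromosome 12)
4297	f	24	pre-B	pb	PBX1	TCF3::PBX1	220178	OK334241,OK334276	junction carries an insertion derived from FGF6 (chromosome 12)
4297	f	24	pre-B	pb	TCF3	PBX1::TCF3	1178	OK334241,OK334276	junction carries an insertion derived from FGF6 (chromosome 12)
4297	f	24	pre-B	pb	PBX1	PBX1::TCF3	220176	OK334241,OK334276	junction carries an insertion derived from FGF6 (chromosome 12)
4574	m	28	pre-B	bm	TCF3	TCF3::PBX1	1174	ON383218,ON383219	
4574	m	28	pre-B	bm	PBX1	TCF3::PBX1	227739	ON383218,ON383219	
4574	m	28	pre-B	bm	TCF3	PBX1::TCF3	1181	ON383218,ON383219	
4574	m	28	pre-B	bm	PBX1	PBX1::TCF3	227723	ON383218,ON383219	
4641	m	68	pre-B	pb	TCF3	TCF3::PBX1	1185	ON383220	
4641	m	68	pre-B	pb	PBX1	TCF3::PBX1	188751	ON383220	
4946	m	21	pre-B	pb	TCF3	TCF3::PBX1	1179	OK334242	
4946	m	21	pre-B	pb	PBX1	TCF3::PBX1	155038	OK334242	
5077	m	28	pre-B	bm	TCF3	TCF3::PBX1	1178	ON383221	
5077	m	28	pre-B	bm	PBX1	TCF3::PBX1	224786	ON383221	
5341	m	31	pre-B	bm	TCF3	TCF3::PBX1	2908	OK334244,OK334277	
5341	m	31	pre-B	bm	PBX1	TCF3::PBX1	220185	OK334244,OK334277	
5341	m	31	pre-B	bm	TCF3	PBX1::TCF3	2914	OK334244,OK334277	
5341	m	31	pre-B	bm	PBX1	PBX1::TCF3	220183	OK334244,OK334277	
5489	f	39	pre-B	pb	TCF3	TCF3::PBX1	1179	OK334245,OK334278	
5489	f	39	pre-B	pb	PBX1	TCF3::PBX1	224501	OK334245,OK334278	
5489	f	39	pre-B	pb	TCF3	PBX1::TCF3	1190	OK334245,OK334278	
5489	f	39	pre-B	pb	PBX1	PBX1::TCF3	224493	OK334245,OK334278	
5741	f	49	pre-B	bm	TCF3	TCF3::PBX1	1179	OK334246	788 bp inversion in PBX1; two PBX1 breaks on the derivative
5741	f	49	pre-B	bm	PBX1	TCF3::PBX1	122528	OK334246	788 bp inversion in PBX1; two PBX1 breaks on the derivative
5741	f	49	pre-B	bm	PBX1	TCF3::PBX1	123344	OK334246	788 bp inversion in PBX1; two PBX1 breaks on the derivative
5752	f	64	pre-B	bm	TCF3	TCF3::PBX1	1181	OK334247	
5752	f	64	pre-B	bm	PBX1	TCF3::PBX1	204015	OK334247	
5850	m	26	pre-B	unknown	TCF3	TCF3::PBX1	1183	OK334248	sample type printed n.a
5850	m	26	pre-B	unknown	PBX1	TCF3::PBX1	136101	OK334248	sample type printed n.a
5974	m	54	common	pb	TCF3	TCF3::PBX1	1174	OK334249	
5974	m	54	common	pb	PBX1	TCF3::PBX1	131565	OK334249	
6017	f	33	pre-B	pb	TCF3	TCF3::PBX1	1183	ON383222	
6017	f	33	pre-B	pb	PBX1	TCF3::PBX1	153909	ON383222	
6255	m	43	pre-B	bm	TCF3	TCF3::PBX1	1183	OK334250,OK334279	
6255	m	43	pre-B	bm	PBX1	TCF3::PBX1	225679	OK334250,OK334279	
6255	m	43	pre-B	bm	TCF3	PBX1::TCF3	1179	OK334250,OK334279	
6255	m	43	pre-B	bm	PBX1	PBX1::TCF3	225678	OK334250,OK334279	
6610	f	38	pre-B	pb	TCF3	TCF3::PBX1	1184	ON383223	
6610	f	38	pre-B	pb	PBX1	TCF3::PBX1	224282	ON383223	
6776	f	42	pre-B	pb	TCF3	TCF3::PBX1	1183	OK334251	
6776	f	42	pre-B	pb	PBX1	TCF3::PBX1	139327	OK334251	
6840	f	34	common	pb	TCF3	TCF3::PBX1	1028	OK334252	
6840	f	34	common	pb	PBX1	TCF3::PBX1	227189	OK334252	
7236	m	43	pre-B	bm	TCF3	TCF3::PBX1	1175	OK334253	
7236	m	43	pre-B	bm	PBX1	TCF3::PBX1	124284	OK334253	
7281	m	36	pre-B	bm	TCF3	TCF3::PBX1	644	ON383224	
7281	m	36	pre-B	bm	PBX1	TCF3::PBX1	119075	ON383224	
7431	f	47	pre-B	bm	TCF3	TCF3::PBX1	1184	OK334254	
7431	f	47	pre-B	bm	PBX1	TCF3::PBX1	207507	OK334254	
7533	f	49	common	bm	TCF3	TCF3::PBX1	1183	OK334255,OK334280	
7533	f	49	common	bm	PBX1	TCF3::PBX1	143100	OK334255,OK334280	
7533	f	49	common	bm	TCF3	PBX1::TCF3	1179	OK334255,OK334280	
7533	f	49	common	bm	PBX1	PBX1::TCF3	143096	OK334255,OK334280	
7601	f	69	pre-B	bm	TCF3	TCF3::PBX1	1182	OK334256,OK334281	
7601	f	69	pre-B	bm	PBX1	TCF3::PBX1	220952	OK334256,OK334281	
7601	f	69	pre-B	bm	TCF3	PBX1::TCF3	1183	OK334256,OK334281	
7601	f	69	pre-B	bm	PBX1	PBX1::TCF3	220955	OK334256,OK334281	
7613	m	58	pre-B	bm	TCF3	TCF3::PBX1	1178	OK334257,OK334282	
7613	m	58	pre-B	bm	PBX1	TCF3::PBX1	227012	OK334257,OK334282	
7613	m	58	pre-B	bm	TCF3	PBX1::TCF3	1181	OK334257,OK334282	
7613	m	58	pre-B	bm	PBX1	PBX1::TCF3	227012	OK334257,OK334282	
7911	m	36	pre-B	bm	TCF3	TCF3::PBX1	1185	OK334258	
7911	m	36	pre-B	bm	PBX1	TCF3::PBX1	142906	OK334258	
7979	f	62	pre-B	bm	TCF3	TCF3::PBX1	1179	OK334259	
7979	f	62	pre-B	bm	PBX1	TCF3::PBX1	221756	OK334259	
7979	f	62	pre-B	bm	TCF3	PBX1::TCF3	1181	OK334259	
7979	f	62	pre-B	bm	PBX1	PBX1::TCF3	221756	OK334259	
8697	f	45	common	bm	TCF3	TCF3::PBX1	1171	OK334260,OK334283	
8697	f	45	common	bm	PBX1	TCF3::PBX1	137203	OK334260,OK334283	
8781	m	58	pre-B	bm	TCF3	TCF3::PBX1	2078	OK334261	
8781	m	58	pre-B	bm	PBX1	TCF3::PBX1	224147	OK334261	
ML2764	f	64	pre-B	pb	TCF3	TCF3::PBX1	1183	OK334262	
ML2764	f	64	pre-B	pb	PBX1	TCF3::PBX1	121081	OK334262	
ML4316	f	61	pre-B	pb	TCF3	TCF3::PBX1	1179	OK334263,OK334284	
ML4316	f	61	pre-B	pb	PBX1	TCF3::PBX1	148164	OK334263,OK334284	
ML4316	f	61	pre-B	pb	TCF3	PBX1::TCF3	1176	OK334263,OK334284	
ML4316	f	61	pre-B	pb	PBX1	PBX1::TCF3	148145	OK334263,OK334284	
ML4863	f	40	pre-B	pb	TCF3	TCF3::PBX1	1178	OK334264	
ML4863	f	40	pre-B	pb	PBX1	TCF3::PBX1	142494	OK334264	
ML5319	m	77	pre-B	bm	TCF3	TCF3::PBX1	1185	OK334243	
ML5319	m	77	pre-B	bm	PBX1	TCF3::PBX1	134787	OK334243	
ML5947	f	52	pre-B	pb	TCF3	TCF3::PBX1	1184	OK334265,OK334285	
ML5947	f	52	pre-B	pb	PBX1	TCF3::PBX1	121262	OK334265,OK334285	
ML5947	f	52	pre-B	pb	TCF3	PBX1::TCF3	1179	OK334265,OK334285	
ML5947	f	52	pre-B	pb	PBX1	PBX1::TCF3	121248	OK334265,OK334285	
ML7774	f	41	pre-B	pb	TCF3	TCF3::PBX1	2396	OK334266,OK334286	
ML7774	f	41	pre-B	pb	PBX1	TCF3::PBX1	149737	OK334266,OK334286	
ML7774	f	41	pre-B	pb	TCF3	PBX1::TCF3	2397	OK334266,OK334286	
ML7774	f	41	pre-B	pb	PBX1	PBX1::TCF3	149723	OK334266,OK334286	
ML9516	m	67	pre-B	bm	TCF3	TCF3::PBX1	1182	OK334267	
ML9516	m	67	pre-B	bm	PBX1	TCF3::PBX1	224181	OK334267	
ML9735	f	22	pre-B	bm	TCF3	TCF3::PBX1	3275	OK334268	
ML9735	f	22	pre-B	bm	PBX1	TCF3::PBX1	148531	OK334268	
ML10287	m	24	pre-B	bm	TCF3	TCF3::PBX1	1185	OK334269,OK334287	
ML10287	m	24	pre-B	bm	PBX1	TCF3::PBX1	119745	OK334269,OK334287	
ML10287	m	24	pre-B	bm	TCF3	PBX1::TCF3	1183	OK334269,OK334287	
ML10287	m	24	pre-B	bm	PBX1	PBX1::TCF3	119741	OK334269,OK334287	
ML11220	m	67	pre-B	bm	TCF3	TCF3::PBX1	1178	OK334270	
ML11220	m	67	pre-B	bm	PBX1	TCF3::PBX1	127984	OK334270	
ML11358	f	19	pre-B	pb	TCF3	TCF3::PBX1	1183	OK334271	
ML11358	f	19	pre-B	pb	PBX1	TCF3::PBX1	211236	OK334271	
ML11543	m	46	pre-B	bm	TCF3	TCF3::PBX1	1179	OK334272,OK334288	
ML11543	m	46	pre-B	bm	PBX1	TCF3::PBX1	129745	OK334272,OK334288	
ML11543	m	46	pre-B	bm	TCF3	PBX1::TCF3	1179	OK334272,OK334288	
ML11543	m	46	pre-B	bm	PBX1	PBX1::TCF3	129741	OK334272,OK334288	
ML13676	f	31	common	bm	TCF3	TCF3::PBX1	1183	OK334273	
ML13676	f	31	common	bm	PBX1	TCF3::PBX1	220775	OK334273	
ML13772	f	32	pre-B	bm	TCF3	TCF3::PBX1	1184	OK334274	
ML13772	f	32	pre-B	bm	PBX1	TCF3::PBX1	140140	OK334274	
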