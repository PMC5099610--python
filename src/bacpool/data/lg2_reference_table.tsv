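marker	position_cm	n_positive_clones	fpc_contig	n_mtp_clones	expected_size_kb	miseq_n_scaffolds	miseq_size_kb	hybrid_n_scaffolds	hybrid_size_kb
LcaE169	0	2	ctg2943	2	100.6	15	120.8	4	164.7
Lca342	8.6	8	ctg654	4	418.9	46	560.3	12	653.4
LcaTe0354	10.3	3	ctg157	3	420.2	65	415.8	25	743.8
LcaTe0360	15.2	2	ctg462	3	375.4	46	235.5	1	271.5
Lca182	18.4	6	ctg1122	5	495.0	18	403.8	11	713.6
Lca287	24.4	3	ctg1327	7	587.5	23	593.4	12	894.4
Lca276	28.7	2	Singleton	1	108.8	4	84.9	3	150.8
Lca250	34.6	4	ctg1474	1	151.0	10	127.6	3	194.8
Lca964	37.3	2	ctg564	3	284.2	36	264.9	11	387.4
LcaTe0359	41.1	3	ctg1597	2	182.2	24	241.4	7	402.6
LcaTe0138	42.7	3	ctg2977	3	307.4	12	189.4	7	378.3
Lca562	44.9	2	ctg381	5	493.7	33	299.1	11	541.4
Lca418	48.1	1	ctg1727	2	182.2	17	145.0	7	360.5
Lca480	50.3	7	ctg1876	5	420.2	58	196.2	13	445.3
Lca524	51.3	2	ctg2518	3	198.6	5	148.4	4	347.2
LcaE92	54.4	2	ctg3569	2	258.4	13	186.4	8	359.7
LcaTe0447	55.4	4	ctg2781	2	146.9	7	254.9	3	246.3
Lca371	61.3	5	ctg710	5	480.1	63	461.1	19	784.2
LcaTe0533	64	7	ctg1634	3	243.4	11	203.1	7	371.5
LcaE186	75.7	8	ctg1200	6	488.2	39	332.0	6	465.9
LcaTe0605	81.4	3	ctg1654	2	168.6	12	146.6	3	369.1
LcaB128	97.5	7	ctg677	3	529.0	47	269.8	10	480.5
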