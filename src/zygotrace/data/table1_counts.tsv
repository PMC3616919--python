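# Published per-gene maternal (M) / paternal (P) informative-read counts for staged
# pre-blastoderm embryo pools (stages c3_6 = nuclear cycles 3-6 pooled, c7, c8), with
# transcript size (nt) and intron count annotations. Blank cells mean no informative
# reads were reported at that stage. scw appears twice (distinct rows as printed);
# rows are keyed by row_index. The Egfr size prints as 36.4 in the source table and is
# preserved verbatim (it is not a plausible transcript length; treat as annotation only).
# flags: not_annotated = transcript not annotated; overlaps_Nmd3 = gene overlaps Nmd3;
# single_500bp_region = all reads from one 500 bp region.
row_index	gene	m_c3_6	p_c3_6	m_c7	p_c7	m_c8	p_c8	size_nt	introns	flags	x_linked
0	luna	6	6	12	7	13	9	128861	5		0
1	CG16813	2	7	6	5	24	22	996	0		0
2	zen	25	0	12	0	88	83	1336	1		0
3	CG14014			6	24	653	452	1127	0		0
4	Brd			9	16	291	382	530	0		0
5	bnk			15	15	607	563	1572	0		0
6	sisA			9	13	47	53	768	0		1
7	CG15480			24	12	153	152	501	0		0
8	CG18269			7	9	70	93	603	0		0
9	pn			0	6	3	1	1846	1	overlaps_Nmd3	0
10	CG15876			7	5	61	51	619	0		0
11	CG8960			8	2	663	275	646	0	not_annotated	0
12	amos			20	2	164	124	820	0	not_annotated	0
13	sc			5	1	112	77	1483	0		1
14	Bro			8	0	374	213	745	0		0
15	SNCF					199	109	613	0		0
16	run					229	162	2881	1		1
17	m4					174	121	733	0		0
18	CG13716					65	54	354	0		0
19	l(1)sc					37	29	1095	0		1
20	CG14427					92	36	1162	0		0
21	CG13000					123	54	466	0	not_annotated	0
22	scw					105	88	1409	0		0
23	eve					153	249	1583	1		0
24	esg					151	95	2277	0		0
25	scw					8	9	1409	0		0
26	odd					5	7	2000	1	not_annotated	0
27	Egfr					12	3	36.4	5		0
28	Cpr67B					5	7	1378	1		0
29	w-cup					9	1	1933	1		0
30	CG32532			35	1	7	8	15471	8	single_500bp_region	0
31	roX1					15	6	3748	1		1
32	CG7778					9	3	1079	1	not_annotated	0
33	h					118	130	3285	2		0
34	CG4440					36	15	352	1	not_annotated	0
35	CG15479					10	11	602	0	not_annotated	0
36	CG7203					6	2	989	1		0
37	Bsg25A					37	39	1600	0	not_annotated	0
38	Z600					4	1	300	0	not_annotated	0
39	noc					28	8	3158	1		0
40	sog					23	6	21971	4		0
41	Cyp4g1					4	2	2277	0		0
42	tld					30	22	3778	6		0
43	Prm					5	1	7531	2	not_annotated	0
44	gk					11	5	6071	2		0
45	hkb					5	4	1628	1		0
46	CG14915					16	20	506	0		0
47	spo					22	21	2495	0		0
48	tll					58	39	2059	1		0
49	Kr					25	29	2918	1		0
50	Pepck					76	15	1845	0		0
51	term					32	6	1463	0		0
52	sna					29	25	1677	0		0
53	fd19B					32	22	783	0		0
54	CG3332					5	6	4740	7		0
55	ftz					21	29	1904	1		0
56	CG14317					68	37	1347	0		0
57	CG13711					89	38	743	0		0
58	gt					120	72	1857	1		0
59	Doc1					10	2	3668	5		0
60	CG13427					592	157	438	0		0
61	inx3					5	6	5075	5		0
62	CG15634					195	178	1444	0		0
63	CG34214					15	6	594	1		0
64	Notum					5	2	9273	3		0
65	axo					3	3	57714	25		0
66	slp1					48	47	1458	0		0
67	D					10	2	1711	0		0
68	CG5973					9	1	7764	0		0
69	Ocho					44	29	759	0		0
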