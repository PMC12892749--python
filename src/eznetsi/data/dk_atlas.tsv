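region_id	region_name	hemisphere	vertex_ids
1	lh-bankssts	left	1
2	lh-caudalanteriorcingulate	left	2
3	lh-caudalmiddlefrontal	left	3
4	lh-cuneus	left	4
5	lh-entorhinal	left	5
6	lh-fusiform	left	6
7	lh-inferiorparietal	left	7
8	lh-inferiortemporal	left	8
9	lh-isthmuscingulate	left	9
10	lh-lateraloccipital	left	10
11	lh-lateralorbitofrontal	left	11
12	lh-lingual	left	12
13	lh-medialorbitofrontal	left	13
14	lh-middletemporal	left	14
15	lh-parahippocampal	left	15
16	lh-paracentral	left	16
17	lh-parsopercularis	left	17
18	lh-parsorbitalis	left	18
19	lh-parstriangularis	left	19
20	lh-pericalcarine	left	20
21	lh-postcentral	left	21
22	lh-posteriorcingulate	left	22
23	lh-precentral	left	23
24	lh-precuneus	left	24
25	lh-rostralanteriorcingulate	left	25
26	lh-rostralmiddlefrontal	left	26
27	lh-superiorfrontal	left	27
28	lh-superiorparietal	left	28
29	lh-superiortemporal	left	29
30	lh-supramarginal	left	30
31	lh-frontalpole	left	31
32	lh-temporalpole	left	32
33	lh-transversetemporal	left	33
34	lh-insula	left	34
35	rh-bankssts	right	35
36	rh-caudalanteriorcingulate	right	36
37	rh-caudalmiddlefrontal	right	37
38	rh-cuneus	right	38
39	rh-entorhinal	right	39
40	rh-fusiform	right	40
41	rh-inferiorparietal	right	41
42	rh-inferiortemporal	right	42
43	rh-isthmuscingulate	right	43
44	rh-lateraloccipital	right	44
45	rh-lateralorbitofrontal	right	45
46	rh-lingual	right	46
47	rh-medialorbitofrontal	right	47
48	rh-middletemporal	right	48
49	rh-parahippocampal	right	49
50	rh-paracentral	right	50
51	rh-parsopercularis	right	51
52	rh-parsorbitalis	right	52
53	rh-parstriangularis	right	53
54	rh-pericalcarine	right	54
55	rh-postcentral	right	55
56	rh-posteriorcingulate	right	56
57	rh-precentral	right	57
58	rh-precuneus	right	58
59	rh-rostralanteriorcingulate	right	59
60	rh-rostralmiddlefrontal	right	60
61	rh-superiorfrontal	right	61
62	rh-superiorparietal	right	62
63	rh-superiortemporal	right	63
64	rh-supramarginal	right	64
65	rh-frontalpole	right	65
66	rh-temporalpole	right	66
67	rh-transversetemporal	right	67
68	rh-insula	right	68
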