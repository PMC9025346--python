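name	max_array_len	gc_percent	abundance_percent	assembly_of_max	chromosomes	library_similarity	library_class
272A	5953	44	1.0711	AMDS	X	B1	SINE/B1
11A	13947	50	0.9855	AFTD	9–10	ERV2	LTR/ERV2
49A	2075	32	0.8666	APMK	8	ERV	LTR/ERV
767A	7543	42	0.66232	AMDS	NA	ERV2	LTR/ERV2
6A	36714	59	0.5978	AFTD	5, 6, 8–10
33A	29248	46	0.5119	AFTD	5	SAU1.5	Satellite
79A	12802	34	0.4047	AFTD	5, 9–10, 6, X
25B	14645	49	0.1788	AMDS	9–10
304A	4935	36	0.1365	AFTD	NA	ERV2	LTR/ERV2
72A	40914	39	0.1284	AFTD	1
77A	3456	40	0.0761	APMK	5, 2, 8
84A	2885	39	0.0715	APMK	all	Zn-finger	Gene
26A	28887	45	0.0569	AFTD	X
17A	15866	41	0.0340	APMK	6
65A	3391	39	0.0296	APMK	X	Tc1	DNA/Tc1
25A	13526	43	0.0232	APMK	5
27A	2668	46	0.0172	APMK	6
62A	8036	36	0.0076	APMK	2
18A	11035	49	0.0074	AFTD	6, 2, 9–10
24B	5004	48	0.0004	APMK	7
13A	1769	48	0.0003	APMK	3
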