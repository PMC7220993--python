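strain	geo_complex	lineage	st	ALA1	CDC19	SAPT4	GLN4	PGI1	PGM2	origin
15	A	3	1	1	1	1	1	1	1	Mold-ripened cheese, Canada
20	A	2	2	1	2	1	1	2	2	Mold-ripened cheese, Canada
21	C	1	3	2	3	2	2	2	3	Clotted carrot, Japan
28	A	5	4	1	1	1	1	1	4	Mold-ripened cheese, Canada
34	A	2	2	1	2	1	1	2	2	Mold-ripened cheese, Spain
37	A	2	2	1	2	1	1	2	2	Smear cheese, France
38	A	2	2	1	2	1	1	2	2	Mold-ripened cheese, France
39	A	5	4	1	1	1	1	1	4	Smear cheese, France
40	A	5	4	1	1	1	1	1	4	Smear cheese, France
48	B	4	5	1	1	2	3	2	4	Bioreactor contaminant
70	C	1	3	2	3	2	2	2	3	Smear cheese, Canada
73	A	5	4	1	1	1	1	1	4	Smear cheese, France
74	B	4	6	1	4	2	1	3	5	Grass, France
75	B	4	7	1	5	2	1	4	4	Corn silage, France
76	A	5	8	1	1	1	1	2	4	Milk, France
77	A	3	1	1	1	1	1	1	1	Milk, France
244	C	4	9	3	3	2	4	2	6	Milk, Canada
317	B	4	10	4	4	2	3	2	7	Organic milk, Canada
436	A	2	2	1	2	1	1	2	2	Industrial strain - company A
562	A	5	4	1	1	1	1	1	4	Milk, MPP 1, Canada
563	A	5	4	1	1	1	1	1	4	Milk, Canada
645	A	5	4	1	1	1	1	1	4	Smear cheese, Canada
655	A	5	4	1	1	1	1	1	4	Mold-ripened cheese, Canada
664	B	4	11	4	4	2	1	2	4	Milk, MPP 1, Canada
690	B	4	12	5	6	2	1	4	7	Milk, MPP 3, Canada
1024	A	3	13	5	1	1	1	1	1	Industrial strain - company B
1025	A	3	13	5	1	1	1	1	1	Industrial strain - company B
1026	A	4	14	1	1	1	1	2	8	Industrial strain - company B
1028	A	2	2	1	2	1	1	2	2	Industrial strain - company A
1031	A	3	13	5	1	1	1	1	1	Industrial strain - company A
1032	A	3	13	5	1	1	1	1	1	Industrial strain - company A
1033	A	3	13	5	1	1	1	1	1	Industrial strain - company A
1034	A	2	2	1	2	1	1	2	2	Industrial strain - company A
1035	C	1	15	3	4	2	2	2	3	Industrial strain - company A
1036	A	2	2	1	2	1	1	2	2	Industrial strain - company A
1037	A	3	13	5	1	1	1	1	1	Industrial strain - company A
1038	A	5	4	1	1	1	1	1	4	Industrial strain - company A
1039	A	5	4	1	1	1	1	1	4	Industrial strain - company A
1040	A	5	4	1	1	1	1	1	4	Industrial strain - company A
1041	A	3	1	1	1	1	1	1	1	Industrial strain - company A
1146	A	3	1	1	1	1	1	1	1	Artisanal sheep cheese, Slovakia
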