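#name	length	mw_kda	pi	tm	loc	h2	h5	le1	le2	npa_lb	npa_le	p1	p2	p3	p4	p5
JcPIP1;1	287	30.73	8.60	6	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
JcPIP1;2	287	30.54	8.62	6	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
JcPIP1;3	212	22.57	8.53	6	Plas	F	H	T	R	NPA	NPA	E	S	A	F	W
JcPIP1;4	286	30.46	8.72	6	Plas	F	N	A	R	NPA	NPA	Q	S	A	F	W
JcPIP2;1	284	30.35	8.20	6	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
JcPIP2;2	286	30.60	7.62	6	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
JcPIP2;3	285	30.33	8.67	6	Plas	F	H	T	R	NPA	NPA	Q	S	A	F	W
JcPIP2;4	280	29.91	8.97	6	Plas	F	H	T	R	NPA	NPA	M	S	A	F	W
JcPIP2;5	283	29.67	9.10	6	Plas	F	H	T	R	NPA	NPA	V	S	A	F	W
JcTIP1;1	252	25.97	5.91	6	Plas	H	I	A	V	NPA	NPA	T	S	A	Y	W
JcTIP1;2	252	25.79	4.96	6	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
JcTIP1;3	252	25.79	5.13	6	Vacu	H	I	A	V	NPA	NPA	T	S	A	Y	W
JcTIP1;4	254	26.39	5.83	6	Vacu	H	V	A	V	NPA	NPA	T	S	A	Y	W
JcTIP2;1	248	25.26	5.59	6	Vacu	H	I	G	R	NPA	NPA	T	S	A	Y	W
JcTIP2;2	250	25.34	5.69	6	Vacu	H	I	G	R	NPA	NPA	T	S	A	Y	W
JcTIP3;1	257	27.34	6.49	6	Vacu	H	I	A	R	NPA	NPA	T	A	A	Y	W
JcTIP4;1	247	25.97	6.12	6	Vacu	H	I	A	R	NPA	NPA	T	S	A	Y	W
JcTIP5;1	252	26.01	7.85	6	Vacu	N	V	G	S	NPA	NPA	I	A	A	Y	W
JcNIP1;1	275	29.27	9.21	6	Plas	W	V	A	R	NPA	NPA	F	S	A	Y	L
JcNIP2;1	291	30.80	8.85	6	Plas	G	S	G	R	NPA	NPA	L	T	A	Y	I
JcNIP3;1	277	30.04	8.50	6	Plas	W	V	A	R	NPA	NPA	F	S	A	F	L
JcNIP3;2	280	30.04	5.52	6	Vacu	W	M	A	R	NPA	NPA	F	S	A	Y	I
JcNIP4;1	263	27.82	5.89	6	Plas	W	V	A	R	NPA	NPA	F	S	A	Y	I
JcNIP5;1	298	30.85	8.87	6	Plas	S	I	A	R	NPA	NPV	F	T	A	Y	L
JcNIP6;1	307	31.37	8.71	6	Plas	S	I	A	R	NPS	NPV	L	T	A	Y	L
JcNIP7;1	265	28.17	7.00	6	Plas	A	V	G	R	NPA	NPA	Y	S	A	Y	I
JcXIP1;1	294	32.27	6.05	6	Plas	I	I	V	R	SPI	NPA	M	C	A	F	W
JcXIP2;1	303	32.29	6.59	6	Plas	I	T	V	R	NPV	NPA	L	C	A	F	W
JcSIP1;1	239	25.79	9.58	6	Plas	V	L	P	N	NPT	NPA	I	A	A	Y	W
JcSIP1;2	242	26.01	9.73	6	Vacu	A	L	P	N	NPT	NPA	M	A	A	Y	W
JcSIP1;3	243	26.00	10.02	6	Extr	S	L	P	N	NPT	NPA	M	A	A	Y	W
JcSIP2;1	241	26.37	9.57	6	Vacu	S	L	G	S	NPL	NPA	F	V	A	Y	W
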