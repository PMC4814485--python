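#name	scaffold	locus	predicted_start	predicted_end	identified_start	identified_end	chromosome	cds_len	gene_len	est_hits	expressed	splice_est	splice_read	introns	utr5	utr3	at_ortholog	pt_ortholog	rc_ortholog	hb_ortholog
JcPIP1;1	Scaffold11	JCGZ_01316	1070240	1071401	1069930	1071930	LG10	864	1162	66	Yes	-	-	-	-	-	AtPIP1;1	PtPIP1;3	RcPIP1;3	HbPIP1;2
JcPIP1;2	Scaffold660	JCGZ_20580	1435150	1432165	1435625	1431654	LG9	864	2986	26	Yes	Yes	Yes	-	-	-	AtPIP1;1	PtPIP1;3	RcPIP1;4	HbPIP1;4
JcPIP1;3	Scaffold843	JCGZ_25040	422332	423912	422332	423912	LG6	639	1581	-	-	-	-	-	-	-	AtPIP1;1	PtPIP1;5	RcPIP1;1	HbPIP1;1
JcPIP1;4	Scaffold392	JCGZ_14388	3034258	3032720	3034588	3032444	LG8	861	1539	1	Yes	-	Yes	-	-	-	AtPIP1;1	PtPIP1;5	RcPIP1;5	HbPIP1;5
JcPIP2;1	Scaffold473	JCGZ_16499	528238	527109	528393	526820	LG6	855	1185	17	Yes	-	-	-	-	-	AtPIP2;4	PtPIP2;7	RcPIP2;1	HbPIP2;1
JcPIP2;2	Scaffold18	JCGZ_05520	1671011	1673093	1670693	1673533	LG2	861	1654	9	Yes	-	Yes	-	-	-	AtPIP2;4	PtPIP2;8	RcPIP2;3	HbPIP2;4
JcPIP2;3	Scaffold63	JCGZ_20043	224967	221774	225179	220824	LG10	858	3194	7	Yes	-	Yes	-	-	-	AtPIP2;5	PtPIP2;4	RcPIP2;2	HbPIP2;6
JcPIP2;4	Scaffold540	JCGZ_18836	689605	690883	689338	691284	LG2	843	1939	50	Yes	-	Yes	-	-	-	AtPIP2;8	PtPIP2;2	RcPIP2;4	HbPIP2;7
JcPIP2;5	Scaffold872	JCGZ_25357	143964	140778	144178	140525	LG9	852	3187	4	Yes	-	Yes	-	-	-	AtPIP2;8	PtPIP2;9	RcPIP2;4	HbPIP2;9
JcTIP1;1	Scaffold473	JCGZ_16577	1075843	1074990	1076252	1074449	LG6	759	854	186	Yes	Yes	Yes	-	-	-	AtTIP1;1	PtTIP1;6	RcTIP1;1	HbTIP1;2
JcTIP1;2	Scaffold528	JCGZ_18448	657196	655908	657291	655693	LG10	759	1289	-	Yes	-	Yes	-	-	-	AtTIP1;3	PtTIP1;1	RcTIP1;2	HbTIP1;5
JcTIP1;3	Scaffold18	JCGZ_05655	2916885	2918031	2916391	2919915	LG2	759	1070	-	Yes	-	-	-	-	-	AtTIP1;3	PtTIP1;1	RcTIP1;3	HbTIP1;7
JcTIP1;4	Scaffold18	JCGZ_05430	531115	532094	531009	532425	LG2	765	980	-	Yes	-	-	-	-	-	AtTIP1;1	PtTIP1;7	RcTIP1;4	HbTIP1;3
JcTIP2;1	Scaffold191	JCGZ_06324	1941464	1942389	1941333	1942605	LG2	747	1304	40	Yes	-	-	-	-	-	AtTIP2;1	PtTIP2;2	RcTIP2;1	HbTIP2;1
JcTIP2;2	Scaffold137	JCGZ_03415	265803	267097	265749	267564	LG9	753	1295	3	Yes	Yes	Yes	-	-	-	AtTIP2;2	PtTIP2;4	RcTIP2;2	HbTIP2;3
JcTIP3;1	Scaffold23	JCGZ_08448	71937	71012	72143	70768	LG8	774	927	28	Yes	-	-	-	-	-	AtTIP3;2	PtTIP3;2	RcTIP3;1	HbTIP3;1
JcTIP4;1	Scaffold211	JCGZ_07757	4725255	4724215	4725438	4724041	LG11	744	1041	1	Yes	-	-	-	-	-	AtTIP4;1	PtTIP4;1	RcTIP4;1	HbTIP4;1
JcTIP5;1	Scaffold906	JCGZ_26261	2139472	2140440	2138913	2140560	LG5	759	969	-	Yes	-	-	-	-	-	AtTIP5;1	PtTIP5;2	RcTIP5;1	HbTIP5;1
JcNIP1;1	Scaffold684	JCGZ_21622	2673636	2675513	2673356	2675705	LG3	828	1878	-	Yes	-	-	-	-	-	AtNIP1;2	PtNIP1;1	RcNIP1;1	HbNIP1;1
JcNIP2;1	Scaffold617	JCGZ_19849	96979	94697	97540	94138	LG9	876	2283	-	Yes	-	Yes	-	-	-	-	PtNIP2;1	RcNIP2;1	HbNIP2;1
JcNIP3;1	Scaffold46	JCGZ_15791	1520636	1519402	1520800	1519402	LG4	834	1235	-	Yes	-	-	-	-	-	-	PtNIP3;1	RcNIP3;1	HbNIP3;1
JcNIP3;2	Scaffold8	JCGZ_24027	126258	127532	126113	127676	LG7	843	1275	-	Yes	-	-	-	-	-	-	PtNIP3;1	RcNIP3;1	HbNIP3;1
JcNIP4;1	Scaffold1210	JCGZ_02488	12952	14295	12952	14295	LG9	792	1344	1	Yes	-	-	-	-	-	AtNIP4;2	PtNIP4;2	RcNIP4;2	HbNIP4;2
JcNIP5;1	Scaffold660	JCGZ_20348	126085	128887	124382	130375	LG9	897	2803	2	Yes	-	Yes	-	-	-	AtNIP5;1	PtNIP5;1	RcNIP5;1	HbNIP5;1
JcNIP6;1	Scaffold96	JCGZ_27003	2282049	2284301	2281766	2285794	LG2	924	2253	-	Yes	Yes	Yes	-	-	-	AtNIP6;1	PtNIP6;1	RcNIP6;1	HbNIP6;1
JcNIP7;1	Scaffold119	JCGZ_02114	699621	702542	701200	702613	LG1	798	1124	-	Yes	-	-	-	-	-	AtNIP7;1	PtNIP7;1	RcNIP7;1	HbNIP7;1
JcXIP1;1	Scaffold595	JCGZ_19604	291308	292309	291239	292309	LG2	885	1071	-	-	-	-	-	-	-	-	PtXIP1;1	RcXIP1;3	HbXIP1;1
JcXIP2;1	Scaffold595	JCGZ_19603	288337	289806	288124	289999	LG2	912	1470	-	Yes	-	Yes	-	-	-	-	PtXIP2;1	RcXIP2;1	HbXIP2;1
JcSIP1;1	Scaffold2033	-	-	-	130442	125075	LG6	720	4477	-	Yes	-	Yes	590,3167	329	562	AtSIP1;1	PtSIP1;2	RcSIP1;1	HbSIP1;3
JcSIP1;2	Scaffold1149	JCGZ_01828	248685	247978	248898	247991	LG7	729	729	-	Yes	-	-	-	-	-	AtSIP1;1	PtSIP1;4	RcSIP1;3	HbSIP1;1
JcSIP1;3	Scaffold1149	JCGZ_01827	247059	246328	247514	246040	LG7	732	732	-	Yes	-	-	-	-	-	AtSIP1;1	PtSIP1;4	RcSIP1;3	HbSIP1;1
JcSIP2;1	Scaffold407	JCGZ_14885	34721	25023	35046	24630	LG6	726	6716	-	Yes	-	Yes	-	-	-	AtSIP2;1	PtSIP2;1	RcSIP2;1	HbSIP2;1
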