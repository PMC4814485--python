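#species	common_name	family	organism_type	PIP	TIP	NIP	SIP	XIP	total
Oryza sativa	Rice	Poaceae	Monocot	11	10	10	2	0	33
Zea mays	Maize	Poaceae	Monocot	13	12	5	3	0	33
Hordeum vulgare	Barley	Poaceae	Monocot	20	11	8	1	0	40
Musa acuminate	Banana	Musaceae	Monocot	18	17	9	3	0	47
Arabidopsis thaliana	Arabidopsis	Brassicaceae	Dicot	13	10	9	3	0	35
Brassica rapa	Chinese cabbage	Brassicaceae	Dicot	23	16	15	6	0	60
Brassica oleracea	Cabbage	Brassicaceae	Dicot	25	19	17	6	0	67
Solanum tuberosum	Potato	Solanaceae	Dicot	15	11	10	3	8	47
Solanum lycopersicum	Garden tomato	Solanaceae	Dicot	14	11	12	4	6	47
Glycine max	Soybean	Fabaceae	Dicot	22	23	17	8	2	72
Gossypium hirsutum	Upland cotton	Malvaceae	Dicot	28	23	12	7	1	71
Vitis vinifera	Grapevine	Vitaceae	Dicot	8	11	9	2	2	32
Citrus sinensis	Sweet orange	Rutaceae	Dicot	8	11	9	3	3	34
Phaseolus vulgaris	Common bean	Fabaceae	Dicot	12	13	10	4	2	41
Jatropha curcas	Physic nut	Euphorbiaceae	Dicot	9	9	8	4	2	32
Ricinus communis	Castor bean	Euphorbiaceae	Dicot	10	9	8	4	6	37
Hevea brasiliensis	Rubber tree	Euphorbiaceae	Dicot	15	17	9	4	6	51
Populus trichocarpa	Poplar	Salicaceae	Dicot	15	17	11	6	6	55
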