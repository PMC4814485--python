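#substrate	sdp1	sdp2	sdp3	sdp4	sdp5	sdp6	sdp7	sdp8	sdp9
NH3	F/T	K/L/N/V	F/T	V/L/T	A	D/S	A/H/L	E/P/S	A/R/T
boric acid	T/V	I/V	H/I	P	E	I/L	I/L/T	A/T	A/G/K/P
CO2	I/L/V	I	C	A	I/V	D	W	D	W
H2O2	A/S	A/G	L/V	A/F/L/T/V	I/L/V	H/I/L/Q	F/Y	A/V	P
silicic acid	C/S	F/Y	A/E/L	H/R/Y	G	K/N/T	R	E/S/T	A/K/P/T
urea	H	P	F/I/L/T	A/C/F/L	L/M	A/G/P	G/S	G/S	N
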