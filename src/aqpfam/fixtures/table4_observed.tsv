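#substrate	name	sdp1	sdp2	sdp3	sdp4	sdp5	sdp6	sdp7	sdp8	sdp9
NH3	JcNIP1;1	F	K	F	T	A	D	L	E	T
boric acid	JcPIP1;1	T	I	H	P	E	L	L	T	P
boric acid	JcPIP1;2	T	I	H	P	E	L	L	T	P
boric acid	JcPIP1;3	T	I	H	P	E	L	L	T	P
boric acid	JcNIP2;1	V	V	H	P	E	I	I	A	P
boric acid	JcNIP5;1	T	I	H	P	E	L	L	A	P
boric acid	JcNIP6;1	T	I	H	P	E	L	L	A	P
CO2	JcPIP1;1	I	M	C	A	I	D	W	D	W
CO2	JcPIP1;2	L	I	C	A	I	D	W	D	W
CO2	JcPIP1;4	I	M	C	A	I	D	W	D	W
CO2	JcPIP2;1	I	M	C	A	V	D	W	D	W
CO2	JcPIP2;2	L	M	C	A	V	D	W	D	W
CO2	JcPIP2;4	L	M	C	A	I	D	W	D	W
H2O2	JcPIP1;1	A	G	V	F	I	H	F	V	P
H2O2	JcPIP1;2	A	G	V	F	I	H	F	V	P
H2O2	JcPIP1;4	A	G	V	F	I	H	F	V	P
H2O2	JcPIP2;1	A	G	V	F	I	Q	F	V	P
H2O2	JcPIP2;2	A	G	V	F	I	Q	F	V	P
H2O2	JcPIP2;3	A	G	V	F	I	Q	F	V	P
H2O2	JcPIP2;4	A	G	V	F	I	H	F	V	P
H2O2	JcPIP2;5	A	G	V	L	I	H	F	V	P
H2O2	JcTIP1;2	S	A	L	A	I	H	Y	V	P
H2O2	JcTIP3;1	S	A	L	V	I	H	Y	V	P
H2O2	JcTIP5;1	S	A	L	A	I	Q	Y	V	P
H2O2	JcNIP2;1	A	A	L	L	V	I	Y	V	P
H2O2	JcNIP4;1	S	A	L	L	V	L	Y	A	P
H2O2	JcNIP5;1	S	A	L	V	V	I	Y	V	P
H2O2	JcXIP2;1	A	G	L	A	V	H	F	V	P
silicic acid	JcNIP2;1	G	F	V	H	G	N	R	T	K
urea	JcPIP1;1	H	P	F	F	L	P	G	G	N
urea	JcPIP1;2	H	P	F	F	L	P	G	G	N
urea	JcPIP1;4	H	P	F	F	L	P	G	G	N
urea	JcPIP2;1	H	P	F	F	L	P	G	G	N
urea	JcPIP2;2	H	P	F	F	L	P	G	G	N
urea	JcPIP2;3	H	P	F	F	L	P	G	G	N
urea	JcPIP2;4	H	P	F	F	L	P	G	G	N
urea	JcPIP2;5	H	P	F	L	L	P	G	G	N
urea	JcTIP1;1	H	P	F	F	L	A	G	S	N
urea	JcTIP1;2	H	P	F	F	L	A	G	S	N
urea	JcTIP1;3	H	P	F	F	L	A	G	S	N
urea	JcTIP1;4	H	P	F	F	L	A	G	S	N
urea	JcTIP2;1	H	P	F	A	L	P	G	S	N
urea	JcTIP2;2	H	P	F	A	L	P	G	S	N
urea	JcTIP4;1	H	P	L	L	L	A	G	S	N
urea	JcTIP5;1	H	P	F	A	L	P	G	S	N
urea	JcNIP1;1	H	P	L	A	L	P	G	S	N
urea	JcNIP2;1	H	P	T	A	M	P	G	S	N
urea	JcNIP3;1	H	P	I	A	L	P	G	S	N
urea	JcNIP4;1	H	P	I	A	L	P	G	S	N
urea	JcNIP5;1	H	P	I	A	L	P	G	S	N
urea	JcNIP6;1	H	P	I	A	L	P	G	S	N
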