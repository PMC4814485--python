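#subgroup	count
PIP1	3
PIP2	5
TIP1	4
TIP2	2
TIP3	1
TIP4	1
TIP5	1
NIP1	1
NIP2	1
NIP3	1
NIP4	2
NIP5	1
NIP6	1
NIP7	1
XIP1	1
XIP2	1
XIP3	1
SIP1	2
SIP2	1
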