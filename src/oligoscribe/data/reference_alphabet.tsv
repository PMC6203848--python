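label	unit_mass	role
A	100.0	coding
B	105.0	coding
C	110.0	coding
D	115.0	coding
E	120.0	coding
F	125.0	coding
G	130.0	coding
H	135.0	coding
I	140.0	coding
J	145.0	coding
K	150.0	coding
L	155.0	coding
M	160.0	coding
N	165.0	coding
O	170.0	coding
Z	90.0	spacer
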