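residue	asa_A2
A	115
R	225
N	160
D	150
C	135
Q	180
E	190
G	75
H	195
I	175
L	170
K	200
M	185
F	210
P	145
S	115
T	140
W	255
Y	230
V	155
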