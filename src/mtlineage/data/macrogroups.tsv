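prefix	macro	origin
A	A	EAs
B	B	EAs
D	D	EAs
G	G	EAs
J	JT	WEu
T	JT	WEu
L3	L3*	EAs
M	M*	EAs
M7	M7	EAs
M8	M8	EAs
C	M8	EAs
Z	M8	EAs
M9	M9	EAs
E	M9	EAs
N1	N1	WEu
I	N1	WEu
N2	N2	WEu
W	N2	WEu
N9	N9	EAs
Y	N9	EAs
R	R*	EAs
R0	R0	WEu
H	R0	WEu
HV	R0	WEu
V	R0	WEu
rCRS	R0	WEu
R9	R9	EAs
F	R9	EAs
U	U	WEu
K	U	WEu
X	X	WEu
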