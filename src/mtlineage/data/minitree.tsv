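# synthetic PhyloTree-build-17-style subset: lineage names and
# topology follow the published nomenclature, branch motifs are
# generated (transitions on the packaged synthetic reference)
rCRS	-	
R0	rCRS	512T
HV	R0	16281C 16296C
H	HV	6225C 16220C 16480T
H1	H	124G 12125C
H1b	H1	357C 4928T
H1c	H1	892C 16324C
H1j	H1	82A
H5	H	371T
H5a	H5	31G 13232T
H5a1	H5a	481C 12745G
HV13	HV	156C 2024G 16387G
HV13b	HV13	65C 16308T
HV13b1	HV13b	1654A 9377C 11152C 16184T 16291A
V	HV	16275C
JT	rCRS	14A 239C
J	JT	6792G 16255G
J1	J	16105C
J1b	J1	10764G 16311G 16497A
J1b1	J1b	263C
J1b1b	J1b1	179C
J1b1b1	J1b1b	363G 16395G
J1b2	J1b	16373A 16508G
J1d	J1	218A 4479G
J1d6	J1d	27G 4684C
T	JT	492T 622T 16214G
T2	T	16460T
T2g	T2	16157T
T2g1	T2g	557A 14282A 16089A
T2g1a	T2g1	342T 16303C
U	rCRS	246C 5602T 16066G
U2	U	434T 5079G
U2e	U2	430T 9454C
U2e1	U2e	399C
U2e1a	U2e1	197C 16288C
U2e1a1	U2e1a	7696T 16317G
U2e1b	U2e1	16111G
U4	U	151T 16529C
U4b	U4	16443C 16447A
U4b1	U4b	98G 292C
U4b1a	U4b1	336A 10097T
U4b1a1	U4b1a	498T
U4b1a1a	U4b1a1	10658A 16126C 16236T
U4b1a1a1	U4b1a1a	10839A 16080C
U4b1a4	U4b1a	14208T 16384T
U4d	U4	105A 120G 12430G
U4d2	U4d	74A 8591C
U5	U	42T 255C
U5a	U5	15680T 16376G
U5a1	U5a	268T 426T
U5b	U5	549T 5941A
U5b1	U5b	16172T 16353C
U5b1c	U5b1	561T 5397G
U5b1c2	U5b1c	9110T
U8	U	541T
U8b	U8	16028C 16300C
U8b1	U8b	523C 7437C
U8b1a	U8b1	531G 16415G
U8b1a1	U8b1a	7798C 16160T
K	U8b	288G 16261T
N1	rCRS	12645C 16148G 16516C
N1a	N1	331C
I	N1	213T 16513C
I1	I	277C 534G
I1c	I1	16526G
N2	rCRS	5247G 16202G 16350C
W	N2	143T
W1	W	489G 11386T 16045T
X	rCRS	518G 8783G
X2	X	459G 8790A
A	rCRS	3096G 16505C 16553C
A4	A	60T 193C 4278C
B	rCRS	22G 57A 12072C
B4	B	471G
B5	B	209G 515A
D	rCRS	326C
D4	D	7889T 16341T 16564G
D4b	D4	115C 16366T
D5	D	448C
G	rCRS	16100A 16284T
G2	G	112A 15954G 16557C
G2a	G2	10361T 16492G
M7	rCRS	366G 16337A
M7b	M7	16094C
M7c	M7	2T 15888C
M8	rCRS	167C 3839C 16062C
C	M8	16123C
C4	C	418C 528T 14678T
C4a	C4	297C
Z	M8	546G 11214G 16258T
M9	rCRS	259G 16197T
M9a	M9	9C 16487G
N9	rCRS	201T 505T 12626C
N9a	N9	475A 15859C 16129T
Y	N9	5242G 16398G 16429T
R9	rCRS	249T
F	R9	16152T
F1	F	2535T 16039G 16132C
M10	rCRS	445T 16363G
M11	rCRS	16473C
R1	rCRS	176C 16434C
R2	rCRS	95C 412T 13669T
R11	rCRS	395T 16233G
L3e	rCRS	77T 576G
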