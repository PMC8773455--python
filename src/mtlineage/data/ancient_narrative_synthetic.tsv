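# synthetic narrative fixture: planted arrival trajectories, not real ancient mitogenome metadata
record_id	haplogroup	date_ce	longitude	latitude	site
H5a1_band	H5a1	-500	100	47	band_site
H5a1_precursor	H5a1	-800	70	45	western_site
J1b2_band	J1b2	-500	100	47	band_site
J1b2_precursor	J1b2	-800	70	45	western_site
U2e1b_band	U2e1b	-500	100	47	band_site
U2e1b_precursor	U2e1b	-800	70	45	western_site
U4b1a1a1_band	U4b1a1a1	-500	100	47	band_site
U4b1a1a1_precursor	U4b1a1a1	-800	70	45	western_site
U4b1a4_band	U4b1a4	-500	100	47	band_site
U4b1a4_precursor	U4b1a4	-800	70	45	western_site
T2g_band	T2g1	-500	100	47	band_site
T2g_precursor	T2g1	-800	70	45	western_site
T2g1a_band	T2g1a	300	100	47	band_site
T2g1a_precursor	T2g1a	-350	45	45	western_site
I1c_band	I1c	-400	95	47	band_site
I1c_precursor	I1c	-900	40	45	western_site
J1b1b1_band	J1b1b1	400	105	47	band_site
J1b1b1_precursor	J1b1b1	-200	50	45	western_site
J1d6_band	J1d6	-300	110	47	band_site
U2e1a1_band	U2e1a1	500	98	47	band_site
U2e1a1_precursor	U2e1a1	100	48	45	western_site
U4d2_band	U4d2	-600	92	47	band_site
U4d2_precursor	U4d2	-700	30	45	western_site
U5b1c2_band	U5b1c2	-200	102	47	band_site
U8b1a1_band	U8b1a1	-100	96	47	band_site
U8b1a1_precursor	U8b1a1	-2000	25	45	western_site
U5a1_band	U5a1	-2800	101	47	band_site
U5a1_precursor	U5a1	-3300	60	45	western_site
H1b_band	H1b	-2000	99	47	band_site
X2_band	X2	-1500	93	47	band_site
X2_precursor	X2	-2500	35	45	western_site
W1_band	W1	-1200	104	47	band_site
K_band	K	-1100	108	47	band_site
K_precursor	K	-4000	20	45	western_site
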