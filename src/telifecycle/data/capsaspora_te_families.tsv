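family	te_class	copy_number	fle	solo	rnaseq_reads	identical_copies	ltr_identity_range	pi_total	pi_fle	pi_solo	tajima_d	sig
Cocv1	LTR	64	39	25	437027	47	99.3-100	0.075	0.011	0.160	-2.439	*
Cocv2	LTR	33	23	10	22365	21	99.3-100	0.008	0.007	0.009	-2.396	*
Cocv3	LTR	26	16	10	72753	15	100	0.021	0.012	0.033	-2.118	*
Cocv4	LTR	17	1	16	80	2	100	0.174	0.000	0.184	-2.103	*
Cocv5	LTR	22	14	8	62990	4	99.7-100	0.042	0.043	0.042	-1.526	ns
CoL1	nonLTR	12			15275	0		0.048			-0.183	ns
CoL2	nonLTR	51			63284	16		0.069			-1.478	ns
CoL3	nonLTR	30			777	0		0.164			-1.925	*
CoL4	nonLTR	47			49002	5		0.102			-2.186	*
Cobalt1	DNA	34			29065	16		0.013			0.326	ns
Cobalt2	DNA	18			8902	4		0.032			0.262	ns
Cobalt3	DNA	1			805	0						
CoCACTA1	DNA	18			2629	4		0.028			0.210	ns
CoCACTA2	DNA	35			1344	9		0.086			n/a	
Com1	DNA	19			26930	12		0.015			1.669	ns
Com2	DNA	12			4941	0		0.197			-1.297	ns
Cop1	DNA	51			65112	20		0.004			-2.078	*
Cop2	DNA	44			56126	17		0.081			1.135	ns
Cop3	DNA	27			46819	11		0.047			-2.003	*
Cop4	DNA	37			32779	17		0.011			-1.405	ns
Cop5	DNA	31			457	5		0.171			-1.518	ns
CoTc1	DNA	83			164264	34		0.007			-2.669	***
CoTc2	DNA	14			1566	0		0.022			-1.124	ns
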