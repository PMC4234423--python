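chip	quadrant	sample	assay_id	mean_cov	min_cov	max_cov	sd_cov
chip1	1	Normal1	PTEN-4	766.1	66	1232	314.0
chip1	2	Normal1	PTEN-4	494.6	40	800	204.5
chip1	3	MCF7	PTEN-4	450.0	37	720	176.9
chip1	4	MCF7	PTEN-4	520.2	42	879	216.8
chip2	1	786-O	PTEN-4	732.0	57	1224	310.2
chip2	2	HCT-15	PTEN-4	486.7	33	823	201.9
chip2	3	MDA-MB-231	PTEN-4	386.4	29	643	159.5
chip2	4	OVCAR-5	PTEN-4	282.8	19	452	107.8
chip3	1	MOLT-4	PTEN-4	683.9	48	1094	272.9
chip3	2	DU-145	PTEN-4	364.0	24	610	144.1
chip3	3	SN12C	PTEN-4	234.9	23	388	90.1
chip3	4	BT-549	PTEN-4	422.5	45	643	150.1
chip4	1	IGROV-1	PTEN-4	409.0	35	626	141.1
chip4	2	CCRF-CEM	PTEN-4	0.4	0	2	0.7
chip4	3	PC3	PTEN-4	0.4	0	1	0.5
chip4	4	HCT116	PTEN-4	627.4	62	1033	246.2
chip5	1	Normal1 A	PTEN-4	611.7	58	984	245.1
chip5	2	ACHN	PTEN-4	426.6	28	699	176.5
chip5	3	HT-29	PTEN-4	256.0	26	396	90.6
chip5	4	MCF7	PTEN-4	503.0	38	796	196.7
chip6	1	Normal1	PTEN-4	602.4	39	1015	261.2
chip6	2	Normal2	PTEN-4	378.8	33	613	145.4
chip6	3	Normal2	PTEN-4	225.6	18	344	83.2
chip6	4	RPMI-8226	PTEN-4	365.8	36	571	135.1
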