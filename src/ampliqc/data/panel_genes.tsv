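gene	ensembl_id	n_exons	target_region	n_primers	capture_size
BRCA1	ENSG00000012048	12	1693	33	14202
MLH1	ENSG00000076242	16	6025	18	7416
PALB2	ENSG00000083093	9	9027	19	8072
MSH2	ENSG00000095002	8	4605	20	8095
TGFBR1	ENSG00000106799	63	13147	25	11159
PHOX2B	ENSG00000109132	34	9371	4	2028
MSH6	ENSG00000116062	27	10930	16	7441
VHL	ENSG00000134086	16	10701	4	1896
APC	ENSG00000134982	3	3737	35	15085
BRCA2	ENSG00000139618	10	4328	43	20068
NOTCH1	ENSG00000148400	3	538	32	16514
ATM	ENSG00000149311	3	565	63	26598
TGFBR2	ENSG00000163513	16	3307	19	7987
PTEN	ENSG00000171862	13	4003	10	4329
NF2	ENSG00000186575	4	342	17	6972
FLCN	ENSG00000264187	12	1495	13	5586
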