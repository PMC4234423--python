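gene	sample	chrom	pos	cdna	protein	mut_class	assay_id	qpcr_call	ref_depth	alt_depth
APC	HT-29	5	112173848	c.2557G>T	p.E853*	snv		ok	428	214
APC	HCT-15	5	112175539	c.4248delC	p.I1417fs*2	small_indel		ok	2	963
APC	HT-29	5	112175957	c.4666_4667insA	p.T1556fs*3	small_indel		ok	608	355
APC	HCT-15	5	112177787	c.6496C>T	p.R2166*	snv		ok	247	360
BRCA2	HCT-15	13	32912089	c.3599_3600delGT	p.C1200fs*1	small_indel		ok	165	114
BRCA2	HCT-15	13	32913837	c.5351delA	p.N1784fs*7	small_indel		ok	272	302
MLH1	DU-145	3	37038108	c.117-2A>T	p.?	snv		ok	0	476
MLH1	IGROV-1	3	37070378	c.1513delA	p.S505fs*3	small_indel		ok	5	605
MLH1	CCRF-CEM	3	37042536	c.298C>T	p.R100*	snv		ok	354	400
MLH1	HCT116	3	37056000	c.755C>A	p.S252*	snv		ok	0	30
MLH1	CCRF-CEM	3	37056036	c.790+1G>A	p.?	snv		ok	3	6
MSH6	IGROV-1	2	48030647	c.3261delC	p.F1088fs*2	small_indel		ok	65	650
MSH6	HCT-15	2	48032121	c.3511_3516>T	p.D1171fs*4	complex		ok	551	0
MSH6	HCT-15	2	48025990	c.868delC	p.L290fs*1	small_indel		ok	214	230
NF2	SN12C	22	30032739	c.115-1G>C	p.?	snv		ok	0	599
NF2	ACHN	22	30032794	c.169C>T	p.R57*	snv		ok	2	772
NF2	MDA-MB-231	22	30057209	c.691G>T	p.E231*	snv		ok	1	817
NOTCH1	CCRF-CEM	9	139399362	c.4783_4784ins36	p.R1595>PRLPHNSSFHFLR	small_indel		ok	96	23
NOTCH1	MOLT-4	9	139390649	c.7544_7545delCT	p.P2515fs*4	small_indel		ok	143	155
PTEN	PC3	10	89685270	c.165_1212del1048	p.R55fs*1	large_deletion	PTEN-4	deletion	0	0
PTEN	786-O	10	89692961	c.445C>T	p.Q149*	snv		ok	0	910
PTEN	CCRF-CEM	10	89653782	c.80_492del413	p.?	large_deletion	PTEN-4	deletion	0	0
PTEN	MOLT-4	10	89717775	c.800delA	p.K267fs*9	small_indel		ok	34	1499
PTEN	BT-549	10	89720672	c.823delG	p.V275fs*1	small_indel		ok	3	159
VHL	786-O	3	10183842	c.311delG	p.G104fs*55	small_indel		ok	5	250
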