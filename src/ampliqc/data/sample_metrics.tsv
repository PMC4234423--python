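sample	n_pcr_replicates	total_reads	mapped_frac	on_target_frac	duplicate_frac	amplicon_mean_cov	amplicon_sd_cov	exon_mean_cov	exon_sd_cov
Normal1-duplicate-B	2	951169	0.977	0.79	0.156	542.7	334.9	427.9	409.4
BT-549	2	1031471	0.9740000000000001	0.779	0.166	567.7	365.2	451.1	436.8
CCRF-CEM	2	894547	0.977	0.764	0.152	498.4	356.9	403.3	413.9
HCT-15	2	826606	0.977	0.8029999999999999	0.14	486.5	327.9	384.1	387.4
MOLT-4	2	1271883	0.9790000000000001	0.773	0.172	747.0	460.3	589.9	561.2
HCT116	2	1384151	0.977	0.72	0.21	724.4	524.5	589.1	609.5
Normal1-duplicate-A	2	1608833	0.9790000000000001	0.743	0.20600000000000002	877.3	536.2	692.3	658.2
SN12C	2	472237	0.978	0.847	0.098	294.1	199.9	233.5	233.6
IGROV-1	2	672337	0.978	0.797	0.11599999999999999	404.9	281.6	325.8	329.2
DU-145	2	723007	0.978	0.821	0.12300000000000001	434.7	273.1	346.9	332.1
MDA-MB-231	2	769668	0.977	0.812	0.132	461.8	315.7	367.6	373.4
OVCAR-5	2	659926	0.973	0.8109999999999999	0.131	386.5	293.4	308.1	332.7
786-O	2	1167234	0.9790000000000001	0.7909999999999999	0.172	684.6	463.9	543.9	549.2
MCF7-B	2	1053960	0.978	0.778	0.17300000000000001	588.1	398.9	472.1	473.4
PC3	2	566416	0.978	0.799	0.115	329.9	252.1	267.3	287.9
MCF7-A	2	1299077	0.976	0.76	0.193	703.5	465.2	569.0	558.0
RPMI-8226	1	1037872	0.975	0.772	0.16899999999999998	575.4	394.6	462.1	461.8
Normal2-singleton-A	1	806612	0.977	0.799	0.145	461.2	296.8	367.2	355.5
MCF7	1	1193431	0.976	0.753	0.182	647.8	441.9	515.4	513.5
Normal1-singleton-A	1	1227019	0.9790000000000001	0.747	0.17300000000000001	688.5	450.0	543.0	533.9
Normal2-singleton-B	1	571558	0.977	0.828	0.113	340.9	227.4	274.5	268.0
HT-29	1	578229	0.978	0.8170000000000001	0.11599999999999999	340.1	243.2	273.1	280.7
Normal1-singleton-B	1	1070055	0.978	0.759	0.156	615.2	393.4	488.2	472.0
ACHN	1	853092	0.978	0.792	0.149	486.6	327.2	387.2	384.2
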