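sample	replicate_labels	replicate_counts	union	union_indels	intersect	intersect_indels	concordant	discordant
Normal1	Duplicate-A;Duplicate-B;Singleton-A;Singleton-B	145;133;141;143	168	15	120	10	118	2
MCF7	Duplicate-A;Duplicate-B;Singleton	76;77;84	86	16	72	10	69	3
Normal2	Singleton-A;Singleton-B	134;133	149	14	121	11	119	2
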