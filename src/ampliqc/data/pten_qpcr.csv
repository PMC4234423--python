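chip,quadrant,sample,assay_id,cq,endpoint_fluorescence,replicate_index
chip1,1,Normal1,PTEN-4,19.9,3409.9,1
chip1,2,Normal1,PTEN-4,20.1,3219.8,1
chip1,3,MCF7,PTEN-4,23.7,3592.8,1
chip1,4,MCF7,PTEN-4,23.2,3204.2,1
chip2,1,786-O,PTEN-4,22.4,5000.1,1
chip2,2,HCT-15,PTEN-4,19.8,4097.8,1
chip2,3,MDA-MB-231,PTEN-4,19.2,4508.4,1
chip2,4,OVCAR-5,PTEN-4,19.9,4188.0,1
chip3,1,MOLT-4,PTEN-4,19.6,3499.5,1
chip3,2,DU-145,PTEN-4,18.7,4686.3,1
chip3,3,SN12C,PTEN-4,19.0,3725.0,1
chip3,4,BT-549,PTEN-4,20.0,4036.6,1
chip4,1,IGROV-1,PTEN-4,20.0,4000.3,1
chip4,2,CCRF-CEM,PTEN-4,40.0,0.0,1
chip4,3,PC3,PTEN-4,40.0,0.0,1
chip4,4,HCT116,PTEN-4,20.1,3906.9,1
chip5,1,Normal1 A,PTEN-4,20.2,4424.1,1
chip5,2,ACHN,PTEN-4,20.2,3996.0,1
chip5,3,HT-29,PTEN-4,20.2,4239.3,1
chip5,4,MCF7,PTEN-4,20.5,4035.4,1
chip6,1,Normal1,PTEN-4,20.5,2955.7,1
chip6,2,Normal2,PTEN-4,20.7,3482.0,1
chip6,3,Normal2,PTEN-4,21.1,3440.0,1
chip6,4,RPMI-8226,PTEN-4,21.9,3660.0,1
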