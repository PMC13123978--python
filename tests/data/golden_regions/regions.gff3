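##gff-version 3
ISO00001_c1	capspec	prophage	2140	36139	.	.	.	ID=ISO00001_c1:0.0;isolate=ISO00001;stage=final;completeness=88.1;confidence=high
ISO00002_c1	capspec	prophage	13105	47104	.	.	.	ID=ISO00002_c1:0.0;isolate=ISO00002;stage=final;completeness=55.9;confidence=low
ISO00003_c1	capspec	prophage	32235	66234	.	.	.	ID=ISO00003_c1:0.0;isolate=ISO00003;stage=final;completeness=71.6;confidence=high
ISO00004_c1	capspec	prophage	33945	67944	.	.	.	ID=ISO00004_c1:0.0;isolate=ISO00004;stage=final;completeness=90.3;confidence=high
ISO00005_c1	capspec	prophage	49184	83183	.	.	.	ID=ISO00005_c1:0.0;isolate=ISO00005;stage=final;completeness=78;confidence=medium
ISO00006_c1	capspec	prophage	56382	90381	.	.	.	ID=ISO00006_c1:0.0;isolate=ISO00006;stage=final;completeness=90.8;confidence=high
ISO00007_c1	capspec	prophage	48686	82685	.	.	.	ID=ISO00007_c1:0.0;isolate=ISO00007;stage=final;completeness=60.3;confidence=high
ISO00008_c1	capspec	prophage	53185	87184	.	.	.	ID=ISO00008_c1:0.0;isolate=ISO00008;stage=final;completeness=86.6;confidence=high
ISO00009_c1	capspec	prophage	49680	83679	.	.	.	ID=ISO00009_c1:0.0;isolate=ISO00009;stage=final;completeness=54.2;confidence=low
ISO00010_c1	capspec	prophage	5072	39071	.	.	.	ID=ISO00010_c1:0.0;isolate=ISO00010;stage=final;completeness=87.1;confidence=high
ISO00011_c1	capspec	prophage	44909	78908	.	.	.	ID=ISO00011_c1:0.0;isolate=ISO00011;stage=final;completeness=79.2;confidence=high
ISO00012_c1	capspec	prophage	16540	50539	.	.	.	ID=ISO00012_c1:0.0;isolate=ISO00012;stage=final;completeness=64.5;confidence=medium
ISO00013_c1	capspec	prophage	54330	88329	.	.	.	ID=ISO00013_c1:0.0;isolate=ISO00013;stage=final;completeness=74.7;confidence=low
ISO00014_c1	capspec	prophage	504	34503	.	.	.	ID=ISO00014_c1:0.0;isolate=ISO00014;stage=final;completeness=97.1;confidence=medium
ISO00015_c1	capspec	prophage	33829	67828	.	.	.	ID=ISO00015_c1:0.0;isolate=ISO00015;stage=final;completeness=59.8;confidence=low
ISO00016_c1	capspec	prophage	57394	91393	.	.	.	ID=ISO00016_c1:0.0;isolate=ISO00016;stage=final;completeness=70.4;confidence=medium
ISO00017_c1	capspec	prophage	44678	78677	.	.	.	ID=ISO00017_c1:0.0;isolate=ISO00017;stage=final;completeness=79.6;confidence=medium
ISO00018_c1	capspec	prophage	46120	80119	.	.	.	ID=ISO00018_c1:0.0;isolate=ISO00018;stage=final;completeness=72.5;confidence=low
ISO00019_c1	capspec	prophage	49936	83935	.	.	.	ID=ISO00019_c1:0.0;isolate=ISO00019;stage=final;completeness=64.1;confidence=high
ISO00020_c1	capspec	prophage	48248	82247	.	.	.	ID=ISO00020_c1:0.0;isolate=ISO00020;stage=final;completeness=69.4;confidence=low
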