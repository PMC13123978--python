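region_id	isolate_id	contig_id	start	end	completeness	confidence
ISO00001_c1:0.0	ISO00001	ISO00001_c1	2139	36139	88.1	high
ISO00002_c1:0.0	ISO00002	ISO00002_c1	13104	47104	55.9	low
ISO00003_c1:0.0	ISO00003	ISO00003_c1	32234	66234	71.6	high
ISO00004_c1:0.0	ISO00004	ISO00004_c1	33944	67944	90.3	high
ISO00005_c1:0.0	ISO00005	ISO00005_c1	49183	83183	78.0	medium
ISO00006_c1:0.0	ISO00006	ISO00006_c1	56381	90381	90.8	high
ISO00007_c1:0.0	ISO00007	ISO00007_c1	48685	82685	60.3	high
ISO00008_c1:0.0	ISO00008	ISO00008_c1	53184	87184	86.6	high
ISO00009_c1:0.0	ISO00009	ISO00009_c1	49679	83679	54.2	low
ISO00010_c1:0.0	ISO00010	ISO00010_c1	5071	39071	87.1	high
ISO00011_c1:0.0	ISO00011	ISO00011_c1	44908	78908	79.2	high
ISO00012_c1:0.0	ISO00012	ISO00012_c1	16539	50539	64.5	medium
ISO00013_c1:0.0	ISO00013	ISO00013_c1	54329	88329	74.7	low
ISO00014_c1:0.0	ISO00014	ISO00014_c1	503	34503	97.1	medium
ISO00015_c1:0.0	ISO00015	ISO00015_c1	33828	67828	59.8	low
ISO00016_c1:0.0	ISO00016	ISO00016_c1	57393	91393	70.4	medium
ISO00017_c1:0.0	ISO00017	ISO00017_c1	44677	78677	79.6	medium
ISO00018_c1:0.0	ISO00018	ISO00018_c1	46119	80119	72.5	low
ISO00019_c1:0.0	ISO00019	ISO00019_c1	49935	83935	64.1	high
ISO00020_c1:0.0	ISO00020	ISO00020_c1	48247	82247	69.4	low
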