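isolate_id	contig_id	region_index	start	end	completeness	confidence
ISO00001	ISO00001_c1	0	4139	34139	88.1	high
ISO00002	ISO00002_c1	0	15104	45104	55.9	low
ISO00003	ISO00003_c1	0	34234	64234	71.6	high
ISO00004	ISO00004_c1	0	35944	65944	90.3	high
ISO00005	ISO00005_c1	0	51183	81183	78.0	medium
ISO00006	ISO00006_c1	0	58381	88381	90.8	high
ISO00007	ISO00007_c1	0	50685	80685	60.3	high
ISO00008	ISO00008_c1	0	55184	85184	86.6	high
ISO00009	ISO00009_c1	0	51679	81679	54.2	low
ISO00010	ISO00010_c1	0	7071	37071	87.1	high
ISO00011	ISO00011_c1	0	46908	76908	79.2	high
ISO00012	ISO00012_c1	0	18539	48539	64.5	medium
ISO00013	ISO00013_c1	0	56329	86329	74.7	low
ISO00014	ISO00014_c1	0	2503	32503	97.1	medium
ISO00015	ISO00015_c1	0	35828	65828	59.8	low
ISO00016	ISO00016_c1	0	59393	89393	70.4	medium
ISO00017	ISO00017_c1	0	46677	76677	79.6	medium
ISO00018	ISO00018_c1	0	48119	78119	72.5	low
ISO00019	ISO00019_c1	0	51935	81935	64.1	high
ISO00020	ISO00020_c1	0	50247	80247	69.4	low
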