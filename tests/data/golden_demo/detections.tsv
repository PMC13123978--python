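isolate_id	contig_id	contig_length	start	end	tool
ISO00001	ISO00001_c1	100000	3970	34573	virsorter
ISO00001	ISO00001_c1	100000	4026	34555	phispy
ISO00002	ISO00002_c1	100000	14857	45594	virsorter
ISO00002	ISO00002_c1	100000	14789	45129	phispy
ISO00003	ISO00003_c1	100000	34219	64645	virsorter
ISO00003	ISO00003_c1	100000	34165	64449	phispy
ISO00004	ISO00004_c1	100000	35491	66151	virsorter
ISO00004	ISO00004_c1	100000	35639	66323	phispy
ISO00005	ISO00005_c1	100000	51038	81357	virsorter
ISO00005	ISO00005_c1	100000	50781	81571	phispy
ISO00006	ISO00006_c1	100000	58037	88834	virsorter
ISO00006	ISO00006_c1	100000	58334	88667	phispy
ISO00007	ISO00007_c1	100000	50543	81081	virsorter
ISO00007	ISO00007_c1	100000	50256	80725	phispy
ISO00008	ISO00008_c1	100000	54778	85561	virsorter
ISO00008	ISO00008_c1	100000	55135	85481	phispy
ISO00009	ISO00009_c1	100000	51363	82129	virsorter
ISO00009	ISO00009_c1	100000	51562	81817	phispy
ISO00010	ISO00010_c1	100000	6723	37141	virsorter
ISO00010	ISO00010_c1	100000	6757	37560	phispy
ISO00011	ISO00011_c1	100000	46806	76941	virsorter
ISO00011	ISO00011_c1	100000	46878	77404	phispy
ISO00012	ISO00012_c1	100000	18276	48581	virsorter
ISO00012	ISO00012_c1	100000	18262	48858	phispy
ISO00013	ISO00013_c1	100000	56227	86443	virsorter
ISO00013	ISO00013_c1	100000	56105	86403	phispy
ISO00014	ISO00014_c1	100000	2501	32653	virsorter
ISO00014	ISO00014_c1	100000	2389	32644	phispy
ISO00015	ISO00015_c1	100000	35481	66243	virsorter
ISO00015	ISO00015_c1	100000	35558	66226	phispy
ISO00016	ISO00016_c1	100000	58901	89442	virsorter
ISO00016	ISO00016_c1	100000	59345	89702	phispy
ISO00017	ISO00017_c1	100000	46338	76698	virsorter
ISO00017	ISO00017_c1	100000	46196	77019	phispy
ISO00018	ISO00018_c1	100000	47854	78272	virsorter
ISO00018	ISO00018_c1	100000	47888	78587	phispy
ISO00019	ISO00019_c1	100000	51604	82340	virsorter
ISO00019	ISO00019_c1	100000	51824	82006	phispy
ISO00020	ISO00020_c1	100000	50098	80742	virsorter
ISO00020	ISO00020_c1	100000	50086	80742	phispy
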