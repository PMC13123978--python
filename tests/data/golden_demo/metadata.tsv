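isolate_id	sc	k_locus	k_confidence	species
ISO00001	SC001	KL1	Good	K. pneumoniae
ISO00002	SC002	KL2	Good	K. pneumoniae
ISO00003	SC003	KL2	Good	K. pneumoniae
ISO00004	SC004	KL1	Good	K. pneumoniae
ISO00005	SC002	KL2	Good	K. pneumoniae
ISO00006	SC003	KL1	Good	K. pneumoniae
ISO00007	SC001	KL1	Good	K. pneumoniae
ISO00008	SC004	KL2	Good	K. pneumoniae
ISO00009	SC002	KL1	Good	K. pneumoniae
ISO00010	SC004	KL1	Good	K. pneumoniae
ISO00011	SC004	KL1	Good	K. pneumoniae
ISO00012	SC001	KL1	Good	K. pneumoniae
ISO00013	SC003	KL1	Good	K. pneumoniae
ISO00014	SC001	KL1	Good	K. pneumoniae
ISO00015	SC001	KL1	Good	K. pneumoniae
ISO00016	SC004	KL1	Good	K. pneumoniae
ISO00017	SC004	KL1	Good	K. pneumoniae
ISO00018	SC001	KL1	Good	K. pneumoniae
ISO00019	SC004	KL1	Good	K. pneumoniae
ISO00020	SC001	KL1	Good	K. pneumoniae
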