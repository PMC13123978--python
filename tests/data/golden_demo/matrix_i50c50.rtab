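Gene	ISO00001	ISO00002	ISO00003	ISO00004	ISO00005	ISO00006	ISO00007	ISO00008	ISO00009	ISO00010	ISO00011	ISO00012	ISO00013	ISO00014	ISO00015	ISO00016	ISO00017	ISO00018	ISO00019	ISO00020
bg0001	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
bg0002	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
bg0003	0	0	1	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
bg0004	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0
bg0005	0	1	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
bg0006	0	1	0	0	0	1	0	0	0	0	0	0	0	0	1	0	0	1	0	0
bg0007	1	0	0	0	1	0	1	1	0	1	1	0	0	0	0	0	0	0	1	0
bg0008	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0
bg0009	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0
bg0010	0	0	0	0	0	0	1	0	1	0	0	0	0	1	0	0	0	0	0	0
rbp_KL1	1	0	0	1	0	1	1	0	1	0	1	1	1	1	1	1	1	1	1	1
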