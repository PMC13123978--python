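cluster_id	x_level	t_level	probability	tcov
bg0003	2004	2004.1.1	0.7929027050752868	0.43204699148678244
bg0004	101	101.1.1	0.9461780568375502	0.3499291551606083
bg0005	2004	2004.1.1	0.5369339379338403	0.3546751171417417
bg0007	101	101.1.1	0.9163565636179738	0.1958572147615591
bg0008	3240	3240.1.1	0.6182346346880012	0.6997333244314793
rbp_KL1	207	207.2.1	0.9796807417511784	0.2216249103873284
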