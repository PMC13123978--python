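cluster_id	kind	target_klocus	sensitivity	fpr	level_map
rbp_KL1	true_rbp	KL1	0.9	0.01	i0c50:rbp_KL1+bg0010;i0c80:rbp_KL1+bg0007;i50c50:rbp_KL1;i50c80:rbp_KL1;i80c50:rbp_KL1_s1,rbp_KL1_s2;i80c80:rbp_KL1
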