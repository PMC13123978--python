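cluster_id	category	probability	qcov	scov
bg0001	lysin	0.9028505702515977	0.6196606605188193	0.8261774835499349
bg0002	integrase	0.9734037965453519	0.8221937624856952	0.8608570361815413
bg0003	terminase	0.7408486579298997	0.4027306557663223	0.8744837017161313
bg0004	terminase	0.8951090813265066	0.6616551881612542	0.5262992919627086
bg0005	portal	0.7603323438942609	0.38099232325247817	0.6226528689820441
bg0006	portal	0.9746928828924233	0.9057265964711252	0.9409548417734452
bg0007	major capsid	0.8196026611657198	0.6489313923624886	0.9583940764415357
bg0008	major capsid	0.8591981896274254	0.7150157749773733	0.8499308704519746
bg0009	portal	0.8047388435832923	0.8171486389120375	0.4516685239835986
bg0010	portal	0.7987355051972084	0.7069890274952322	0.4135735144452928
rbp_KL1	tail fiber	0.9351848556579474	0.7701239436571421	0.6664967883249514
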