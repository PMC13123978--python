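# demo simulation: tiny lineage-structured population with one planted
# capsule-specific cluster (synthetic fixture for the golden-run test)
n_isolates: 20
n_sc: 4
n_kloci: 2
k_switch_rate: 0.1
n_background_clusters: 10
planted_specs:
  - target_klocus: KL1
    sensitivity: 0.9
    fpr: 0.01
    kind: true_rbp
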