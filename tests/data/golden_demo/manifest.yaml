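params:
  config:
    k_switch_rate: 0.1
    n_background_clusters: 10
    n_isolates: 20
    n_kloci: 2
    n_sc: 4
  seed: 42
stage: simulate
tool: capspec
version: 0.1.0
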