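params:
  min_completeness: 50.0
  min_length: 2000
  pad: 2000
stage: merge-regions
tool: capspec
version: 0.1.0
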