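# Clusters-within-clusters structuring with the fixed 3-pair graph.
experiment: hierarchy
seed: 0
output_dir: run-hierarchy
train:
  alpha: 1.0
  epochs: 200
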