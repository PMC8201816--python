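# Component-count recovery on binary-pattern data with 3 feature modules.
experiment: module-recovery
seed: 1
output_dir: run-module-recovery
data:
  n_modules: 3
  n_samples: 512
graph_learn:
  n_trials: 10
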