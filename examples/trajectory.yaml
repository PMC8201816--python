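# Graph learning on bifurcating-trajectory data (smoothing regime:
# k=3 bandwidths, dense penalty graph, alpha=1 are filled in by default).
experiment: trajectory
seed: 0
output_dir: run-trajectory
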