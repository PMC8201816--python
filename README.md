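# gsreg — graph spectral regularization for interpretable hidden layers

Dense neural networks learn useful representations, but the neurons of a
hidden layer carry no spatial or relational organization: which neuron ends
up encoding what is an accident of initialization.  `gsreg` structures a
designated hidden layer of a dense classifier or autoencoder with a **graph
Laplacian smoothness penalty**: neurons are identified with the nodes of a
feature graph `G = (V, E)` with symmetric nonnegative weights `W`, and the
loss becomes

    total = task_loss + α · G(z, L),      G(z, L) = zᵀ L z = ½ Σᵢⱼ Wᵢⱼ (zᵢ − zⱼ)²

where `z` is the layer's activation vector, `L = D − W` the combinatorial
graph Laplacian (`Dᵢᵢ = Σⱼ Wᵢⱼ`), and `α ≥ 0` the regularization weight.
Graph-adjacent neurons are pushed to activate on similar inputs, so the
layer becomes a map that can be read like an imaging modality: per-class
activation maps, localized receptive fields, cluster-detecting "super
nodes".

When no meaningful graph is known a priori, `gsreg` **learns** one by
alternating between (i) building a feature graph from the co-activations of
the layer's neurons with an adaptive-bandwidth Gaussian kernel

    K(zᵢ, zⱼ) = ½ exp(−‖zᵢ−zⱼ‖² / 2σᵢ²) + ½ exp(−‖zᵢ−zⱼ‖² / 2σⱼ²)

(σᵢ = distance from neuron i's activation profile to its k-th nearest
neighboring profile) and (ii) training with the penalty on that graph.
Smoothing reinforces the co-activation structure it was built from, while
the task loss stops the graph from collapsing; on data with `n` independent
feature modules the learned graph fragments into `n` connected components.

The package targets tabular numeric data (samples × features) such as bulk
or single-cell expression matrices — optionally PCA-reduced — but applies to
any dense-network setting.

## Worked example: recovering feature modules

Binary-pattern data with 3 independent feature modules (the binary codes
0…7 replicated with `N(0, 0.1²)` noise), a 6-unit structured embedding,
and the alternating graph-learning procedure:

```python
from gsreg import (
    GraphLearnConfig, ModuleDataSpec, StructuredModelSpec,
    generate_module_data, learn_graph,
)

x, module_ids, base = generate_module_data(ModuleDataSpec(n_modules=3, n_samples=512, seed=1))
spec = StructuredModelSpec(task="autoencoding", layer_sizes=(3, 24, 6), batch_norm=True)
result = learn_graph(spec, x, GraphLearnConfig(seed=1))

print("components:", result.components.n_components)
print("labels:    ", result.components.labels)
```

```
components: 3
labels:     [0 1 2 2 0 1]
```

The learned graph has exactly 3 connected components — one per ground-truth
module — and the component labels show which embedding neurons pair up:
neurons (0, 4), (1, 5) and (2, 3) have become duplicate detectors for one
bit each.  `result.graph_snapshots` holds the kernel graph at each outer
iteration for "graph evolves over time" plots.

The same machinery drives the other experiments from the command line:

```
gsreg run --config examples/module_recovery.yaml --seed 1 --out run/
gsreg generate --kind hierarchy --out data.csv --labels labels.csv
```

Each run writes its artifacts (edge-list TSV graphs, CSV loss traces, PNG
activation maps) plus a `manifest.json` echoing the fully resolved
configuration, so any experiment can be rerun from its manifest alone.

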