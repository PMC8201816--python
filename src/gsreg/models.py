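"""Dense networks with one graph-structured layer.

A :class:`StructuredModel` is a plain multi-layer perceptron — classifier
(softmax + cross-entropy) or autoencoder (mirrored decoder + MSE) — in which
one hidden layer is designated the *structured layer*.  Training minimizes

    task loss + alpha * penalty(z)

where ``z`` are the structured-layer activations and the penalty is the
graph spectral regularizer ``z^T L z`` (batch mean), an elementwise L1/L2
activation penalty, or nothing.  The networks here are small, so forward,
backward and the Adam update are implemented directly on numpy arrays;
given a seed, initialization and batch shuffling are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graphs import FeatureGraph, gsr_penalty, gsr_penalty_grad

__all__ = [
    "StructuredModelSpec",
    "TrainConfig",
    "StructuredModel",
    "build_model",
    "composite_loss",
    "train",
    "compare_regularizers",
    "ConfigurationError",
]

REGULARIZERS = ("none", "gsr", "l1", "l2")


class ConfigurationError(ValueError):
    """Invalid model/training configuration."""


@dataclass(frozen=True)
class StructuredModelSpec:
    """Architecture of a dense network with one structured layer.

    Parameters
    ----------
    task : {"classification", "autoencoding"}
    layer_sizes : list of int
        For autoencoders: encoder sizes from input to embedding, e.g.
        ``[15, 10, 6]``; the decoder mirrors the encoder back to the input
        dimension.  For classifiers: input, hidden sizes, and number of
        classes, e.g. ``[2, 32, 3]``.
    structured_layer_index : int, optional
        0-based index among the network's hidden layers carrying the graph.
        Defaults to the embedding (autoencoder) or last hidden layer
        (classifier).
    activation : str
        Hidden nonlinearity; ``relu`` (default) or ``tanh``.
    batch_norm : bool
        Standardize the structured layer's pre-activations over the batch
        (zero mean, unit variance per unit; no learnable scale/shift).
        This pins the activation scale, which would otherwise let the
        network shrink the structured layer to dodge an activation penalty
        while the decoder compensates.  Inference uses running statistics
        accumulated during training.
    """

    task: str
    layer_sizes: tuple[int, ...]
    structured_layer_index: int | None = None
    activation: str = "relu"
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("classification", "autoencoding"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        object.__setattr__(self, "layer_sizes", tuple(self.layer_sizes))
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ConfigurationError(f"bad layer_sizes {self.layer_sizes}")
        if self.activation not in ("relu", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        n_hidden = len(self.full_layer_sizes) - 2
        idx = self.structured_layer_index
        if idx is None:
            # embedding for autoencoders, last hidden layer for classifiers
            idx = len(self.layer_sizes) - 2
            if self.task == "classification":
                idx = len(self.layer_sizes) - 3
        if not 0 <= idx < n_hidden:
            raise ConfigurationError(
                f"structured_layer_index {idx} out of range for "
                f"{n_hidden} hidden layers"
            )
        object.__setattr__(self, "structured_layer_index", idx)

    @property
    def full_layer_sizes(self) -> tuple[int, ...]:
        """All layer widths input -> output, decoder mirrored for AEs."""
        if self.task == "autoencoding":
            return self.layer_sizes + self.layer_sizes[-2::-1]
        return self.layer_sizes

    @property
    def embedding_dim(self) -> int:
        """Width of the structured layer (= graph node count when attached)."""
        return self.full_layer_sizes[self.structured_layer_index + 1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for :func:`train`.

    ``alpha`` is the regularization weight on the penalty; ``regularizer``
    selects the penalty applied to the structured-layer activations.
    """

    alpha: float = 0.0
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    regularizer: str = "none"
    coefficient_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            # lr = 0 is allowed: a degenerate "evaluate only" run
            raise ConfigurationError("learning_rate must be >= 0")
        if self.regularizer not in REGULARIZERS:
            raise ConfigurationError(
                f"regularizer must be one of {REGULARIZERS}, got {self.regularizer!r}"
            )


class StructuredModel:
    """Dense network exposing (task output, structured-layer activations).

    Weights are Glorot-uniform initialized from the construction seed.  Use
    :meth:`forward` for inference; :func:`train` drives learning.
    """

    def __init__(self, spec: StructuredModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = spec.full_layer_sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        # running statistics for batch norm on the structured layer
        self.bn_mean = np.zeros(spec.embedding_dim)
        self.bn_var = np.ones(spec.embedding_dim)
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5

    # -- forward -----------------------------------------------------------

    def _act(self, x: np.ndarray) -> np.ndarray:
        if self.spec.activation == "relu":
            return np.maximum(x, 0.0)
        return np.tanh(x)

    def _act_grad(self, pre: np.ndarray) -> np.ndarray:
        if self.spec.activation == "relu":
            return (pre > 0).astype(float)
        return 1.0 - np.tanh(pre) ** 2

    def _forward_cached(self, x: np.ndarray, training: bool = False):
        """Forward pass keeping pre-activations (and BN cache) for backprop."""
        n_layers = len(self.weights)
        z_layer = self.spec.structured_layer_index
        pre, post = [], [x]
        bn_cache = None
        h = x
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = h @ w + b
            if li == n_layers - 1:  # output layer
                pre.append(a)
                if self.spec.task == "classification":
                    e = np.exp(a - a.max(axis=1, keepdims=True))
                    h = e / e.sum(axis=1, keepdims=True)
                else:
                    h = a
            else:
                if self.spec.batch_norm and li == z_layer:
                    if training:
                        mu, var = a.mean(axis=0), a.var(axis=0)
                        self.bn_mean = (
                            self.bn_momentum * self.bn_mean
                            + (1 - self.bn_momentum) * mu
                        )
                        self.bn_var = (
                            self.bn_momentum * self.bn_var
                            + (1 - self.bn_momentum) * var
                        )
                    else:
                        mu, var = self.bn_mean, self.bn_var
                    invstd = 1.0 / np.sqrt(var + self.bn_eps)
                    a = (a - mu) * invstd
                    bn_cache = (a, invstd)
                pre.append(a)  # post-BN pre-activation for act_grad
                h = self._act(a)
            post.append(h)
        return pre, post, bn_cache

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(output, structured_layer_activations)``.

        Output is class probabilities for classifiers and the
        reconstruction for autoencoders.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _, post, _ = self._forward_cached(x)
        return post[-1], post[self.spec.structured_layer_index + 1]

    def structured_activations(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class predictions (classification only)."""
        if self.spec.task != "classification":
            raise ConfigurationError("predict() requires a classification model")
        return np.argmax(self.forward(x)[0], axis=1)

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def save(self, path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            layer_sizes=np.asarray(self.spec.layer_sizes),
            task=np.asarray(self.spec.task),
            structured_layer_index=np.asarray(self.spec.structured_layer_index),
            activation=np.asarray(self.spec.activation),
            batch_norm=np.asarray(self.spec.batch_norm),
            bn_mean=self.bn_mean,
            bn_var=self.bn_var,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "StructuredModel":
        with np.load(path) as data:
            spec = StructuredModelSpec(
                task=str(data["task"]),
                layer_sizes=tuple(int(s) for s in data["layer_sizes"]),
                structured_layer_index=int(data["structured_layer_index"]),
                activation=str(data["activation"]),
                batch_norm=bool(data["batch_norm"]),
            )
            model = cls(spec)
            model.weights = [data[f"W{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
            model.bn_mean = data["bn_mean"]
            model.bn_var = data["bn_var"]
        return model


def build_model(spec: StructuredModelSpec, seed: int = 0) -> StructuredModel:
    """Deterministically initialize a :class:`StructuredModel`."""
    return StructuredModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# Losses


def _activation_penalty(
    activations: np.ndarray, graph: FeatureGraph | None, config: TrainConfig
) -> float:
    z = np.atleast_2d(activations)
    if config.regularizer == "gsr":
        if graph is None:
            raise ConfigurationError("regularizer 'gsr' requires a FeatureGraph")
        if z.shape[1] != graph.n_nodes:
            raise ConfigurationError(
                f"structured layer has {z.shape[1]} units but graph has "
                f"{graph.n_nodes} nodes"
            )
        return gsr_penalty(z, graph)
    if config.regularizer == "l1":
        return float(np.abs(z).mean())
    if config.regularizer == "l2":
        return float((z**2).mean())
    return 0.0


def composite_loss(
    task_loss: float,
    activations: np.ndarray,
    graph: FeatureGraph | None,
    config: TrainConfig,
) -> float:
    """``task_loss + alpha * penalty`` for the configured regularizer."""
    return float(task_loss) + config.alpha * _activation_penalty(
        activations, graph, config
    )


def _task_loss_and_grad(
    task: str, output: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    b = output.shape[0]
    if task == "classification":
        # target: integer labels; output: softmax probabilities
        p = np.clip(output[np.arange(b), target], 1e-12, None)
        loss = float(-np.log(p).mean())
        grad = output.copy()
        grad[np.arange(b), target] -= 1.0
        return loss, grad / b  # gradient w.r.t. output-layer pre-activation
    diff = output - target
    loss = float((diff**2).mean())
    return loss, 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _backward(
    model: StructuredModel,
    x: np.ndarray,
    target: np.ndarray,
    graph: FeatureGraph | None,
    config: TrainConfig,
) -> tuple[float, float, list[np.ndarray], list[np.ndarray]]:
    """One forward/backward pass; returns (task_loss, penalty, dW, db)."""
    spec = model.spec
    pre, post, bn_cache = model._forward_cached(x, training=True)
    output = post[-1]
    z_idx = spec.structured_layer_index  # layer index; activation is post[z_idx+1]
    z = post[z_idx + 1]

    task_loss, dout = _task_loss_and_grad(spec.task, output, target)
    penalty = _activation_penalty(z, graph, config)

    n_layers = len(model.weights)
    dW = [None] * n_layers
    db = [None] * n_layers
    # delta = gradient w.r.t. pre-activation of current layer; for the
    # softmax/CE and MSE/linear output layers dout already is that gradient
    delta = dout
    for li in range(n_layers - 1, -1, -1):
        dW[li] = post[li].T @ delta
        db[li] = delta.sum(axis=0)
        if li == 0:
            break
        dh = delta @ model.weights[li].T  # grad w.r.t. post[li]
        if li - 1 == z_idx and config.alpha > 0:
            dh = dh + config.alpha * _penalty_grad(z, graph, config)
        delta = dh * model._act_grad(pre[li - 1])
        if li - 1 == z_idx and spec.batch_norm:
            # backprop through the (parameter-free) batch standardization
            ahat, invstd = bn_cache
            delta = invstd * (
                delta
                - delta.mean(axis=0)
                - ahat * (delta * ahat).mean(axis=0)
            )
    return task_loss, penalty, dW, db


def _penalty_grad(
    z: np.ndarray, graph: FeatureGraph | None, config: TrainConfig
) -> np.ndarray:
    if config.regularizer == "gsr":
        return gsr_penalty_grad(z, graph)
    if config.regularizer == "l1":
        return np.sign(z) / z.size
    if config.regularizer == "l2":
        return 2.0 * z / z.size
    return np.zeros_like(z)


def train(
    model: StructuredModel,
    data: np.ndarray,
    labels: np.ndarray | None = None,
    graph: FeatureGraph | None = None,
    config: TrainConfig = TrainConfig(),
) -> tuple[StructuredModel, pd.DataFrame]:
    """Train in place with Adam; returns the model and a per-epoch trace.

    The trace has columns ``epoch, task_loss, penalty, composite`` (batch
    averages within each epoch) and satisfies
    ``composite == task_loss + alpha * penalty`` at every row.  Shuffling
    is driven by ``config.seed`` so identical configurations reproduce
    identical traces.
    """
    x = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("training data contains non-finite values")
    if model.spec.task == "classification":
        if labels is None:
            raise ConfigurationError("classification requires labels")
        target_all = np.asarray(labels)
    else:
        target_all = x
    if config.regularizer == "gsr":
        if graph is None:
            raise ConfigurationError("regularizer 'gsr' requires a FeatureGraph")
        if model.spec.embedding_dim != graph.n_nodes:
            raise ConfigurationError(
                f"structured layer width {model.spec.embedding_dim} != "
                f"graph node count {graph.n_nodes}"
            )

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), config.learning_rate)
    n = x.shape[0]
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        task_sum = pen_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            task_loss, penalty, dW, db = _backward(
                model, x[idx], target_all[idx], graph, config
            )
            if not np.isfinite(task_loss) or not np.isfinite(penalty):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(task={task_loss}, penalty={penalty})"
                )
            opt.step(model.parameters(), dW + db)
            task_sum += task_loss
            pen_sum += penalty
            n_batches += 1
        task_avg = task_sum / n_batches
        pen_avg = pen_sum / n_batches
        rows.append(
            {
                "epoch": epoch,
                "task_loss": task_avg,
                "penalty": pen_avg,
                "composite": task_avg + config.alpha * pen_avg,
            }
        )
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regularizer comparison harness


def _accuracy(model: StructuredModel, x: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict(x) == y).mean())


def compare_regularizers(
    dataset: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    spec: StructuredModelSpec,
    grids: dict[str, list[float]],
    graph: FeatureGraph | None = None,
    base_config: TrainConfig = TrainConfig(),
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated comparison of activation regularizers.

    For every regularizer in ``grids`` the coefficient maximizing accuracy
    on a seeded 80/20 validation split of the training data is selected,
    then the model is retrained on the full training set for
    ``n_replicates`` seeds.  Returns one row per regularizer with the
    selected coefficient and mean +/- sd train and test accuracy, mirroring
    a regularizer-comparison table.

    ``dataset`` is ``(x_train, y_train, x_test, y_test)``.
    """
    x_tr, y_tr, x_te, y_te = dataset
    rows = []
    for reg, grid in grids.items():
        if reg not in REGULARIZERS:
            raise ConfigurationError(f"unknown regularizer {reg!r}")
        if reg != "none" and len(grid) == 0:
            raise ConfigurationError(f"empty coefficient grid for {reg!r}")

        if reg == "none":
            best_coef = None
        else:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(x_tr))
            n_val = max(1, len(x_tr) // 5)
            val_idx, fit_idx = perm[:n_val], perm[n_val:]
            best_coef, best_acc = None, -np.inf
            for coef in grid:
                cfg = replace(base_config, regularizer=reg, alpha=float(coef), seed=seed)
                m = build_model(spec, seed=seed)
                train(m, x_tr[fit_idx], y_tr[fit_idx], graph=graph, config=cfg)
                acc = _accuracy(m, x_tr[val_idx], y_tr[val_idx])
                if acc > best_acc:
                    best_coef, best_acc = float(coef), acc
        tr_accs, te_accs = [], []
        for rep in range(n_replicates):
            cfg = replace(
                base_config,
                regularizer=reg,
                alpha=0.0 if best_coef is None else best_coef,
                seed=seed + 1000 + rep,
            )
            m = build_model(spec, seed=seed + 1000 + rep)
            train(m, x_tr, y_tr, graph=graph, config=cfg)
            tr_accs.append(_accuracy(m, x_tr, y_tr))
            te_accs.append(_accuracy(m, x_te, y_te))
        rows.append(
            {
                "regularizer": reg,
                "coefficient": np.nan if best_coef is None else best_coef,
                "train_accuracy_mean": float(np.mean(tr_accs)),
                "train_accuracy_sd": float(np.std(tr_accs, ddof=1)) if n_replicates > 1 else 0.0,
                "test_accuracy_mean": float(np.mean(te_accs)),
                "test_accuracy_sd": float(np.std(te_accs, ddof=1)) if n_replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
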