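"""Feature graphs, Laplacians, the graph spectral regularization penalty.

A *feature graph* is a weighted undirected graph whose nodes are the neurons
of one hidden layer (the *structured layer*).  The combinatorial Laplacian
``L = D - W`` turns smoothness of an activation vector ``z`` over the graph
into the quadratic form ``z^T L z = 1/2 * sum_ij W_ij (z_i - z_j)^2``, which
is the penalty added to the task loss.

Besides fixed constructors (grid, disjoint pairs, complete graph) this module
builds graphs *from data* with an adaptive-bandwidth Gaussian kernel over
feature activation profiles, and counts connected components of a weighted
graph after thresholding — the statistic used to read off how many feature
modules a learned graph encodes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components as _sp_connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureGraph",
    "KernelParams",
    "ComponentLabeling",
    "laplacian_from_weights",
    "gsr_penalty",
    "grid_graph",
    "disjoint_pairs_graph",
    "complete_graph",
    "adaptive_gaussian_kernel",
    "nn_union_graph",
    "connected_components",
    "DEFAULT_EDGE_THRESHOLD",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
    "write_laplacian_csv",
]

SYMMETRY_TOL = 1e-8  # max allowed |W - W.T| on input adjacencies

# Default edge threshold for binarizing a kernel graph.  The adaptive k=1
# bandwidth pins a mutual nearest pair's affinity at exp(-1/2) ~ 0.607 and
# guarantees every node a one-sided "bridge" affinity of at least
# (1/2) exp(-1/2) ~ 0.303 to its nearest neighbor, however dissimilar.  Any
# cut in (0.31, 0.60) therefore separates genuine mutual co-activation from
# bandwidth artifacts; 0.45 is the midpoint.
DEFAULT_EDGE_THRESHOLD = 0.45


class GraphValidationError(ValueError):
    """Raised when an adjacency matrix or graph parameter is invalid."""


@dataclass(frozen=True)
class FeatureGraph:
    """Symmetric weighted graph over structured-layer neurons.

    Attributes
    ----------
    n_nodes : int
        Number of nodes (neurons).
    weights : ndarray of shape (n_nodes, n_nodes)
        Symmetric nonnegative adjacency ``W`` with zero diagonal.
    laplacian : ndarray of shape (n_nodes, n_nodes)
        Combinatorial Laplacian ``L = D - W``; rows sum to zero and the
        matrix is positive semi-definite.
    node_labels : list of str, optional
        Human-readable node names.
    """

    n_nodes: int
    weights: np.ndarray
    laplacian: np.ndarray
    node_labels: list[str] | None = None

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges with nonzero weight."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the adaptive-bandwidth Gaussian kernel.

    ``k`` is the neighbor index used for the per-feature bandwidth: sigma_i
    is the Euclidean distance from feature i to its k-th nearest *other*
    feature.  ``bandwidth_floor`` guards against zero bandwidth on duplicate
    features; ``standardize`` optionally z-scores each feature's activation
    profile before computing distances.
    """

    k: int = 1
    bandwidth_floor: float = 1e-8
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise GraphValidationError(f"k must be >= 1, got {self.k}")
        if self.bandwidth_floor <= 0:
            raise GraphValidationError(
                f"bandwidth_floor must be positive, got {self.bandwidth_floor}"
            )


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected-component labels of a thresholded feature graph."""

    labels: np.ndarray
    n_components: int
    edge_threshold: float

    def __post_init__(self) -> None:
        if self.n_components != len(np.unique(self.labels)):
            raise GraphValidationError(
                "n_components does not match the number of distinct labels"
            )


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise GraphValidationError(f"adjacency must be square, got shape {w.shape}")
    asym = np.abs(w - w.T)
    if asym.size and asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise GraphValidationError(
            f"adjacency not symmetric: W[{i},{j}]={w[i, j]} vs W[{j},{i}]={w[j, i]}"
        )
    if w.size and w.min() < 0:
        i, j = np.unravel_index(np.argmin(w), w.shape)
        raise GraphValidationError(f"negative weight W[{i},{j}]={w[i, j]}")
    return w


def laplacian_from_weights(
    weights: np.ndarray, node_labels: list[str] | None = None
) -> FeatureGraph:
    """Build a :class:`FeatureGraph` with Laplacian ``L = D - W``.

    The diagonal of ``W`` is zeroed first (self-loops cancel in ``D - W``)
    and the matrix is symmetrized to machine precision.  Rows of the
    returned Laplacian sum to zero exactly up to floating point.
    """
    w = _validate_weights(weights)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    return FeatureGraph(
        n_nodes=w.shape[0], weights=w, laplacian=lap, node_labels=node_labels
    )


def gsr_penalty(activations: np.ndarray, graph: FeatureGraph) -> float:
    """Graph spectral regularization penalty, averaged over the batch.

    For each sample row ``z`` computes the Laplacian quadratic form
    ``z^T L z`` (equal to ``1/2 * sum_ij W_ij (z_i - z_j)^2``) and returns
    the batch mean, so the penalty magnitude is batch-size invariant.

    Parameters
    ----------
    activations : ndarray of shape (n_samples, n_nodes) or (n_nodes,)
        Structured-layer activations.
    graph : FeatureGraph
        Graph whose Laplacian defines smoothness.
    """
    z = np.atleast_2d(np.asarray(activations, dtype=float))
    if z.shape[1] != graph.n_nodes:
        raise GraphValidationError(
            f"activations have {z.shape[1]} columns but graph has "
            f"{graph.n_nodes} nodes"
        )
    # L annihilates constants, so centering each sample leaves the value
    # unchanged while making the constant-signal case exactly zero
    zc = z - z.mean(axis=1, keepdims=True)
    per_sample = np.einsum("si,ij,sj->s", zc, graph.laplacian, zc)
    return float(max(per_sample.mean(), 0.0))


def gsr_penalty_grad(activations: np.ndarray, graph: FeatureGraph) -> np.ndarray:
    """Gradient of :func:`gsr_penalty` w.r.t. the activations (2 L z / B)."""
    z = np.atleast_2d(np.asarray(activations, dtype=float))
    return 2.0 * (z @ graph.laplacian) / z.shape[0]


# ---------------------------------------------------------------------------
# Fixed constructors


def grid_graph(rows: int, cols: int) -> FeatureGraph:
    """4-neighbor lattice with unit weights, row-major node order."""
    if rows < 1 or cols < 1:
        raise GraphValidationError(f"grid dimensions must be >= 1, got {rows}x{cols}")
    n = rows * cols
    w = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                w[i, i + 1] = w[i + 1, i] = 1.0
            if r + 1 < rows:
                w[i, i + cols] = w[i + cols, i] = 1.0
    return laplacian_from_weights(w)


def disjoint_pairs_graph(n_pairs: int) -> FeatureGraph:
    """``n_pairs`` disconnected edges: node 2i joined to node 2i+1.

    The hierarchical-clustering experiments attach this graph to a layer of
    width ``2 * n_pairs`` so each pair can act as a "super node" detecting
    one coarse cluster while its two members split the sub-clusters.
    """
    if n_pairs < 1:
        raise GraphValidationError(f"n_pairs must be >= 1, got {n_pairs}")
    n = 2 * n_pairs
    w = np.zeros((n, n))
    for p in range(n_pairs):
        w[2 * p, 2 * p + 1] = w[2 * p + 1, 2 * p] = 1.0
    return laplacian_from_weights(w)


def complete_graph(n: int) -> FeatureGraph:
    """Complete graph on ``n`` nodes with unit weights (L = n·I − J)."""
    if n < 1:
        raise GraphValidationError(f"n must be >= 1, got {n}")
    w = np.ones((n, n)) - np.eye(n)
    return laplacian_from_weights(w)


# ---------------------------------------------------------------------------
# Kernel-based graph estimation


def adaptive_gaussian_kernel(
    feature_vectors: np.ndarray, params: KernelParams = KernelParams()
) -> FeatureGraph:
    """Adaptive-bandwidth Gaussian affinity graph over features.

    Each row of ``feature_vectors`` is one feature's activation profile
    across samples (i.e. the activation matrix *transposed*).  The affinity
    between features i and j is

        W_ij = 1/2 exp(-d_ij^2 / (2 sigma_i^2)) + 1/2 exp(-d_ij^2 / (2 sigma_j^2))

    with ``d`` the Euclidean distance between profiles and ``sigma_i`` the
    distance from feature i to its ``k``-th nearest other feature (the
    adaptive bandwidth), floored at ``params.bandwidth_floor``.  The adaptive
    bandwidth makes the affinities insensitive to the overall activation
    scale, which is not fixed in a general architecture.

    The diagonal is zeroed (self-loops do not affect the Laplacian); the
    result is exactly symmetric with entries in [0, 1].
    """
    x = np.asarray(feature_vectors, dtype=float)
    if x.ndim != 2:
        raise GraphValidationError("feature_vectors must be 2-D (features x samples)")
    n = x.shape[0]
    if n < 2:
        raise GraphValidationError("need at least 2 features")
    if params.k >= n:
        raise GraphValidationError(
            f"k={params.k} requires at least k+1={params.k + 1} features, got {n}"
        )
    if params.standardize:
        sd = x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)

    d = squareform(pdist(x))
    # k-th nearest *other* feature: sort each row, skip the self-distance 0
    sigma = np.sort(d, axis=1)[:, params.k]
    if np.any(sigma <= params.bandwidth_floor):
        warnings.warn(
            "adaptive bandwidth at or below floor for some features "
            "(duplicate or near-duplicate activation profiles); using "
            f"bandwidth_floor={params.bandwidth_floor}",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma = np.maximum(sigma, params.bandwidth_floor)
    d2 = d**2
    w = 0.5 * np.exp(-d2 / (2.0 * sigma[:, None] ** 2))
    w = w + w.T  # second term is the transpose of the first
    np.fill_diagonal(w, 0.0)
    np.clip(w, 0.0, 1.0, out=w)
    return laplacian_from_weights(w)


def nn_union_graph(graph: FeatureGraph) -> FeatureGraph:
    """Sparsify to the union of each node's single strongest edge.

    Keeps, for every node, only the edge to its highest-affinity neighbor
    (edges kept if either endpoint selects them; original weights
    retained).  Used as the *penalty* graph during graph learning: the
    adaptive kernel's dense output applies near-uniform attraction, whereas
    pulling each neuron only toward its most similar peer keeps merging
    selective.
    """
    w = graph.weights
    n = graph.n_nodes
    keep = np.zeros_like(w, dtype=bool)
    if n > 1:
        for i in range(n):
            j = int(np.argmax(w[i]))
            if w[i, j] > 0:
                keep[i, j] = keep[j, i] = True
    return laplacian_from_weights(
        np.where(keep, w, 0.0), node_labels=graph.node_labels
    )


def connected_components(
    graph: FeatureGraph, edge_threshold: float = DEFAULT_EDGE_THRESHOLD
) -> ComponentLabeling:
    """Connected components of the graph keeping edges with W_ij > threshold.

    Labels are contiguous from 0 and deterministic: the component containing
    the lowest-numbered node gets label 0, and so on.
    """
    if edge_threshold < 0:
        raise GraphValidationError(f"edge_threshold must be >= 0, got {edge_threshold}")
    adj = (graph.weights > edge_threshold).astype(np.int8)
    n_comp, raw = _sp_connected_components(adj, directed=False)
    # relabel so first occurrence order gives the label order
    order = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return ComponentLabeling(labels=labels, n_components=n_comp, edge_threshold=edge_threshold)


# ---------------------------------------------------------------------------
# Graph I/O


def write_edgelist(graph: FeatureGraph, path) -> None:
    """Write one undirected edge per line as ``i<TAB>j<TAB>weight`` (i < j)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for i in range(graph.n_nodes):
            for j in range(i + 1, graph.n_nodes):
                if graph.weights[i, j] != 0:
                    writer.writerow([i, j, repr(float(graph.weights[i, j]))])


def read_edgelist(path, n_nodes: int) -> FeatureGraph:
    """Read an edge-list TSV written by :func:`write_edgelist`."""
    w = np.zeros((n_nodes, n_nodes))
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            i, j, wt = int(row[0]), int(row[1]), float(row[2])
            w[i, j] = w[j, i] = wt
    return laplacian_from_weights(w)


def write_graphml(graph: FeatureGraph, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for i in range(graph.n_nodes):
        for j in range(i + 1, graph.n_nodes):
            if graph.weights[i, j] != 0:
                g.add_edge(i, j, weight=float(graph.weights[i, j]))
    nx.write_graphml(g, path)


def read_graphml(path) -> FeatureGraph:
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes(), key=int)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(data.get("weight", 1.0))
    return laplacian_from_weights(w)


def write_laplacian_csv(graph: FeatureGraph, path) -> None:
    labels = graph.node_labels or [str(i) for i in range(graph.n_nodes)]
    header = ",".join(labels)
    np.savetxt(path, graph.laplacian, delimiter=",", header=header, comments="")
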