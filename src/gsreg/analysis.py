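"""Readouts that turn a structured layer into an interpretable map.

Once a layer is graph-structured, its activations can be read like an
imaging modality: per-class average activation maps, a segmentation of the
layer into class territories, top-percent activation masks for single
inputs, correlation of neurons with external markers grouped by learned
feature module, and assignment of samples to the "super node" (connected
component) that activates most strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .graphs import (
    DEFAULT_EDGE_THRESHOLD,
    ComponentLabeling,
    FeatureGraph,
    connected_components,
)

__all__ = [
    "ActivationMap",
    "Segmentation",
    "class_average_maps",
    "segment_embedding",
    "top_fraction_mask",
    "component_marker_correlation",
    "supernode_assignment",
]

NULL_LABEL = -1


@dataclass(frozen=True)
class ActivationMap:
    """Mean activation of every structured-layer node for one class."""

    values: np.ndarray
    class_id: object

    def as_grid(self, rows: int, cols: int) -> np.ndarray:
        """Reshape the flat node vector to a (rows, cols) grid layout."""
        if rows * cols != self.values.size:
            raise ValueError(
                f"grid {rows}x{cols} incompatible with {self.values.size} nodes"
            )
        return self.values.reshape(rows, cols)


@dataclass(frozen=True)
class Segmentation:
    """Per-node winning class and win margin (top1 - top2 mean activation).

    Nodes whose margin falls below the segmentation floor carry the null
    label ``-1`` — a class can fail to claim any territory.
    """

    labels: np.ndarray
    margins: np.ndarray
    class_ids: tuple


def class_average_maps(activations: np.ndarray, labels) -> list[ActivationMap]:
    """Column-wise mean activation per class, classes in sorted label order."""
    z = np.atleast_2d(np.asarray(activations, dtype=float))
    y = np.asarray(labels)
    if len(y) != z.shape[0]:
        raise ValueError(f"{len(y)} labels for {z.shape[0]} activation rows")
    return [
        ActivationMap(values=z[y == c].mean(axis=0), class_id=c)
        for c in sorted(np.unique(y).tolist())
    ]


def segment_embedding(
    maps: list[ActivationMap], margin_floor: float = 0.0
) -> Segmentation:
    """Assign every node to the class whose average map wins there.

    Ties go to the lowest class index; nodes where the winner's margin over
    the runner-up is below ``margin_floor`` get the null label.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 class maps to segment")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched shapes: {shapes}")
    stack = np.vstack([m.values for m in maps])  # classes x nodes
    winner = np.argmax(stack, axis=0)  # argmax takes the lowest index on ties
    top2 = np.sort(stack, axis=0)[-2:]
    margins = top2[1] - top2[0]
    labels = np.where(margins < margin_floor, NULL_LABEL, winner)
    return Segmentation(
        labels=labels, margins=margins, class_ids=tuple(m.class_id for m in maps)
    )


def top_fraction_mask(activation: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Boolean mask of the ceil(fraction * n) most active nodes.

    Ties at the cutoff are resolved in favor of the lower node index, so
    the mask size is exact.
    """
    v = np.asarray(activation, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("activation vector is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_top = int(np.ceil(fraction * v.size))
    # stable sort on (-value, index): lowest index wins ties
    order = np.lexsort((np.arange(v.size), -v))
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:n_top]] = True
    return mask


def component_marker_correlation(
    embedding_activations: np.ndarray,
    markers: np.ndarray | pd.DataFrame,
    components: ComponentLabeling,
    method: str = "pearson",
) -> pd.DataFrame:
    """Marker-by-neuron correlation table, columns grouped by component.

    Correlates every external marker (e.g. a marker gene's expression per
    sample) with every structured-layer neuron; the column order is sorted
    by (component label, node index), so neurons of one learned feature
    module sit together.  A constant neuron or marker yields correlation 0
    (flagged in ``DataFrame.attrs['constant_columns']``) rather than NaN.
    """
    z = np.atleast_2d(np.asarray(embedding_activations, dtype=float))
    if isinstance(markers, pd.DataFrame):
        marker_names = list(markers.columns)
        m = markers.to_numpy(dtype=float)
    else:
        m = np.atleast_2d(np.asarray(markers, dtype=float))
        marker_names = [f"marker_{i}" for i in range(m.shape[1])]
    if z.shape[0] != m.shape[0]:
        raise ValueError(
            f"{z.shape[0]} activation rows vs {m.shape[0]} marker rows"
        )
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")

    order = np.lexsort((np.arange(z.shape[1]), components.labels))
    corr_fn = pearsonr if method == "pearson" else spearmanr
    constant_cols = []
    table = np.zeros((m.shape[1], z.shape[1]))
    for out_j, node in enumerate(order):
        zc = z[:, node]
        if np.ptp(zc) == 0:
            constant_cols.append(int(node))
            continue
        for i in range(m.shape[1]):
            if np.ptp(m[:, i]) == 0:
                continue
            table[i, out_j] = corr_fn(m[:, i], zc)[0]
    cols = pd.MultiIndex.from_arrays(
        [components.labels[order], order], names=["component", "node"]
    )
    df = pd.DataFrame(table, index=marker_names, columns=cols)
    df.attrs["constant_columns"] = constant_cols
    return df


def supernode_assignment(
    embedding_activations: np.ndarray,
    graph: FeatureGraph,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> np.ndarray:
    """Assign each sample to the component with the largest summed activation.

    Connected components of ``graph`` at ``threshold`` act as super-node
    detectors: a sample belongs to the component whose member neurons are,
    in total, most active on it.  Ties go to the lowest component id.
    """
    z = np.atleast_2d(np.asarray(embedding_activations, dtype=float))
    comp = connected_components(graph, threshold)
    if z.shape[1] != graph.n_nodes:
        raise ValueError(
            f"activations have {z.shape[1]} columns but graph has "
            f"{graph.n_nodes} nodes"
        )
    if comp.n_components == 1:
        warnings.warn(
            "graph has a single connected component; super-node assignment "
            "is degenerate",
            UserWarning,
            stacklevel=2,
        )
    sums = np.zeros((z.shape[0], comp.n_components))
    for c in range(comp.n_components):
        sums[:, c] = z[:, comp.labels == c].sum(axis=1)
    return np.argmax(sums, axis=1)  # argmax ties -> lowest component id
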