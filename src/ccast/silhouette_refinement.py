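"""Iterative silhouette-based refinement of a hard clustering.

A cell's silhouette ``s = (b - a)/max(a, b)`` contrasts its mean distance
to its own cluster (``a``, self excluded) with its mean distance to the
nearest foreign cluster (``b``).  Negative values mark cells that sit
closer, on average, to another cluster than to their own — typically
boundary cells mis-assigned by the density argmax.  Refinement repeatedly
reassigns every negative-silhouette cell to the cluster attaining its
``b`` (its nearest neighbor cluster), recomputes silhouettes, and stops
when no negative values remain, when the cost ``|sum of negative s|``
fails to decrease (the previous partition is kept), or at ``max_iter``.
Clusters emptied along the way disappear, so the refined partition can
have fewer clusters than the input — this is how an intentionally
over-specified mixture fit collapses to the number of real subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_cyto import ExpressionTable

__all__ = ["ClusterLabels", "silhouette_values", "refine_labels"]


@dataclass
class ClusterLabels:
    """Refined hard labels with silhouettes and the refinement cost trace."""

    labels: np.ndarray
    silhouettes: np.ndarray
    cost_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _silhouettes_and_neighbors(
    dist: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Silhouette value and nearest foreign cluster for every cell.

    ``dist`` is the full n x n Euclidean distance matrix.  Singleton-cluster
    cells and cells with ``a = b = 0`` (duplicated points) get s = 0; ties
    for the nearest cluster resolve to the lower cluster id.
    """
    n = dist.shape[0]
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    onehot = (labels[:, None] == ids[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    sums = dist @ onehot  # (n, n_clusters) summed distance to each cluster

    own_col = np.searchsorted(ids, labels)
    own_count = counts[own_col]
    own_sum = sums[np.arange(n), own_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own_count > 1, own_sum / np.maximum(own_count - 1, 1), 0.0)

    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own_col] = np.inf
    nb_col = np.argmin(mean_other, axis=1)  # argmin ties -> lowest id
    b = mean_other[np.arange(n), nb_col]

    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own_count == 1] = 0.0  # singleton convention
    return s, ids[nb_col]


def silhouette_values(table: ExpressionTable, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette values for a hard labeling (Euclidean distance)."""
    labels = np.asarray(labels)
    dist = squareform(pdist(table.values))
    s, _ = _silhouettes_and_neighbors(dist, labels)
    return s


def refine_labels(
    table: ExpressionTable, labels: np.ndarray, max_iter: int = 100
) -> ClusterLabels:
    """Iteratively reassign negative-silhouette cells to their nearest cluster.

    All negative cells are moved simultaneously each iteration (batch
    update); the cost ``|sum of negative silhouettes|`` is tracked and the
    loop terminates the first time it would increase, reverting to the
    previous partition.  Input label ids are preserved (no renumbering), so
    permuting the input ids permutes the output identically.
    """
    labels = np.asarray(labels).copy()
    dist = squareform(pdist(table.values))
    cost_trace: list[float] = []
    prev_labels = labels
    prev_s = np.zeros(len(labels))
    prev_cost = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if len(np.unique(labels)) < 2:
            # refinement collapsed everything into one cluster; silhouettes
            # are undefined there, treat as converged with zero cost
            cost_trace.append(0.0)
            s = np.zeros(len(labels))
            converged = True
            break
        s, neighbor = _silhouettes_and_neighbors(dist, labels)
        neg = s < 0
        cost = float(abs(s[neg].sum()))
        if cost > prev_cost:
            labels, s = prev_labels, prev_s  # keep the better partition
            converged = True
            break
        cost_trace.append(cost)
        if not np.any(neg) or cost == prev_cost:
            converged = True
            break
        prev_labels, prev_s, prev_cost = labels.copy(), s, cost
        labels = labels.copy()
        labels[neg] = neighbor[neg]
    return ClusterLabels(
        labels=labels,
        silhouettes=s,
        cost_trace=np.asarray(cost_trace),
        n_iter=n_iter,
        converged=converged,
    )
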