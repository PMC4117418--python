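"""Tree pruning-level selection and the filter-retrain purification loop.

An unrestricted gating tree is often too deep to execute at a sorter, and
its leaves are rarely pure.  Purification first picks the pruning level
``L`` — the smallest height at which every cluster is the dominant label
of at least one leaf — then iterates: grow a height-``L`` tree, drop from
every leaf the cells not belonging to its dominant cluster (they go to an
"extra bin" kept for inspection), retrain on the retained cells, until all
leaves are pure.  The final tree, trained on the final retained set, is
the sortable gating strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gating_tree import GatingTree, apply_tree, grow_tree
from .io_cyto import ExpressionTable

__all__ = ["PurificationResult", "determine_L", "dominant_filter", "ccast_purify"]


@dataclass
class PurificationResult:
    final_tree: GatingTree
    retained: np.ndarray  # event ids kept
    extra_bin: dict[int, int]  # event id -> round removed at
    L: int
    n_rounds: int
    leaf_to_cluster: dict[int, int]


def _clusters_covered(tree: GatingTree, clusters: np.ndarray) -> bool:
    dominant = {leaf.dominant for leaf in tree.leaves()}
    return set(int(c) for c in clusters) <= dominant


def determine_L(
    table: ExpressionTable,
    labels: np.ndarray,
    alpha: float = 0.05,
    minbucket: int | None = None,
) -> int:
    """Smallest max-height at which every cluster dominates some leaf.

    If even the unrestricted tree fails to cover every cluster, its full
    height is returned with a warning; a single-leaf unrestricted tree over
    more than one cluster is an error (no gate separates anything).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    full = grow_tree(table, labels, alpha=alpha, minbucket=minbucket)
    full_height = full.height
    if full_height == 0:
        if len(clusters) > 1:
            raise ValueError("clusters not separable by any gate (single-leaf tree)")
        return 0  # single cluster: the degenerate single-leaf strategy
    for L in range(1, full_height + 1):
        tree = grow_tree(table, labels, alpha=alpha, minbucket=minbucket, max_height=L)
        if _clusters_covered(tree, clusters):
            return L
    warnings.warn(
        "no height makes every cluster dominant in a leaf; using the full "
        f"tree height {full_height}",
        RuntimeWarning,
        stacklevel=2,
    )
    return full_height


def dominant_filter(
    tree: GatingTree, table: ExpressionTable, labels: np.ndarray
) -> np.ndarray:
    """Event ids of cells matching their leaf's dominant cluster label."""
    labels = np.asarray(labels)
    leaf_of = apply_tree(tree, table)
    dominant = np.array([tree.nodes[nid].dominant for nid in leaf_of])
    return table.event_ids[labels == dominant]


def ccast_purify(
    table: ExpressionTable,
    labels: np.ndarray,
    alpha: float = 0.05,
    minbucket: int | None = None,
    purity: float = 1.0,
    max_rounds: int = 50,
) -> PurificationResult:
    """Filter-retrain loop until every leaf reaches the purity threshold.

    ``purity=1.0`` (the default) demands exactly pure leaves; lowering it
    tolerates leaves whose dominant-cluster fraction meets the threshold,
    which is useful for noisy data.  A round that would empty a cluster
    entirely aborts with a diagnostic, and the loop is guarded at
    ``max_rounds``.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    L = determine_L(table, labels, alpha=alpha, minbucket=minbucket)

    current = table
    cur_labels = labels
    extra_bin: dict[int, int] = {}
    n_rounds = 0
    while True:
        n_rounds += 1
        if n_rounds > max_rounds:
            raise RuntimeError(f"purification did not converge in {max_rounds} rounds")
        tree = grow_tree(current, cur_labels, alpha=alpha, minbucket=minbucket, max_height=L)
        impure = [leaf for leaf in tree.leaves() if leaf.purity < purity]
        if not impure:
            break
        leaf_of = apply_tree(tree, current)
        dominant = np.array([tree.nodes[nid].dominant for nid in leaf_of])
        impure_ids = {leaf.id for leaf in impure}
        in_impure = np.isin(leaf_of, list(impure_ids))
        keep = ~(in_impure & (cur_labels != dominant))
        if keep.all():
            break  # nothing left to remove; leaves stay below threshold
        removed_labels = np.unique(cur_labels[~keep])
        for cl in removed_labels:
            if not np.any(cur_labels[keep] == cl):
                raise RuntimeError(
                    f"purification removed every cell of cluster {int(cl)}"
                )
        for ev in current.event_ids[~keep]:
            extra_bin[int(ev)] = n_rounds
        current = current.subset_events(keep)
        cur_labels = cur_labels[keep]

    if not _clusters_covered(tree, clusters):
        warnings.warn(
            "final tree does not have every cluster dominant in a leaf",
            RuntimeWarning,
            stacklevel=2,
        )
    leaf_to_cluster = {leaf.id: int(leaf.dominant) for leaf in tree.leaves()}
    return PurificationResult(
        final_tree=tree,
        retained=current.event_ids.copy(),
        extra_bin=extra_bin,
        L=L,
        n_rounds=n_rounds,
        leaf_to_cluster=leaf_to_cluster,
    )
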