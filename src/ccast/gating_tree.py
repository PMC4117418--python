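"""Conditional-inference gating tree over markers.

The gating strategy is represented as a binary decision tree: every
internal node carries a marker and a split point ``c`` (cells with value
``<= c`` go left), every leaf a subpopulation with its cluster-label
composition.  Tree growth follows the conditional-inference recipe, which
avoids the variable-selection bias of impurity-based CART:

1. at each node, test every marker for association with the cluster labels
   using the permutation-framework linear statistic of Strasser & Weber —
   the quadratic form ``(t - mu)' Sigma^+ (t - mu)`` with the exact
   conditional moments, referred to a chi-square with df = rank(Sigma);
2. Bonferroni-adjust the per-marker p-values and stop if the smallest
   exceeds the nominal level ``alpha``, else select the smallest;
3. choose the split point on the selected marker as the candidate value
   maximizing the absolute standardized two-sample linear statistic, with
   at least ``minbucket`` cells on each side;
4. recurse until stopping, purity, minimum node size, or ``max_height``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .io_cyto import ExpressionTable

__all__ = [
    "GatingNode",
    "GatingTree",
    "SplitProfile",
    "association_test",
    "select_split_variable",
    "best_binary_split",
    "grow_tree",
    "apply_tree",
]

#: sentinel returned by :func:`select_split_variable` when no marker is
#: significantly associated with the labels at the node
STOP = None


@dataclass
class GatingNode:
    id: int
    kind: str  # "internal" | "leaf"
    marker: str | None = None
    split_point: float | None = None
    p_value: float | None = None
    children: tuple[int, int] | None = None  # (left: <= c, right: > c)
    composition: dict | None = None
    dominant: int | None = None
    purity: float | None = None
    size: int = 0


@dataclass
class SplitProfile:
    """Standardized split statistic at every admissible candidate value."""

    candidates: np.ndarray
    statistics: np.ndarray
    argmax: int


@dataclass
class GatingTree:
    nodes: dict[int, GatingNode] = field(default_factory=dict)
    root: int = 0

    def node(self, node_id: int) -> GatingNode:
        return self.nodes[node_id]

    def leaves(self) -> list[GatingNode]:
        return [n for n in self.nodes.values() if n.kind == "leaf"]

    @property
    def markers_used(self) -> tuple[str, ...]:
        seen: list[str] = []
        for n in self.nodes.values():
            if n.kind == "internal" and n.marker not in seen:
                seen.append(n.marker)
        return tuple(sorted(seen))

    @property
    def height(self) -> int:
        def depth(nid: int) -> int:
            node = self.nodes[nid]
            if node.kind == "leaf":
                return 0
            return 1 + max(depth(c) for c in node.children)

        return depth(self.root)

    def path_to(self, leaf_id: int) -> list[tuple[str, float, str]]:
        """Ordered gate list (marker, threshold, side) from root to a leaf."""
        parent = {}
        for n in self.nodes.values():
            if n.kind == "internal":
                parent[n.children[0]] = (n, "<=")
                parent[n.children[1]] = (n, ">")
        gates = []
        nid = leaf_id
        while nid != self.root:
            node, side = parent[nid]
            gates.append((node.marker, node.split_point, side))
            nid = node.id
        return gates[::-1]

    def structure_signature(self) -> tuple:
        """Marker hierarchy with branch sides, ignoring split values."""

        def sig(nid: int) -> tuple:
            node = self.nodes[nid]
            if node.kind == "leaf":
                return ("leaf",)
            return (node.marker, sig(node.children[0]), sig(node.children[1]))

        return sig(self.root)

    def internal_path_signatures(self) -> dict[tuple, int]:
        """Map (marker, side)-path signature -> internal node id."""
        out: dict[tuple, int] = {}

        def walk(nid: int, prefix: tuple) -> None:
            node = self.nodes[nid]
            if node.kind == "leaf":
                return
            key = prefix + (node.marker,)
            out[key] = nid
            walk(node.children[0], prefix + ((node.marker, "<="),))
            walk(node.children[1], prefix + ((node.marker, ">"),))

        walk(self.root, ())
        return out


# ---------------------------------------------------------------------------
# Permutation-framework statistics
# ---------------------------------------------------------------------------


def _class_indicators(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    return classes, (labels[:, None] == classes[None, :]).astype(float)


def association_test(
    x: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Permutation-framework test of association between a marker and labels.

    The linear statistic is ``t_j = sum_i w_i x_i 1(y_i = j)``; its exact
    conditional mean and covariance under permutations of ``y`` are

        mu = (sum w x) * pi,
        Sigma = V(h) * (w. * sum w x^2 - (sum w x)^2) / (w. - 1),

    with ``pi`` the class proportions and ``V(h) = diag(pi) - pi pi'``.
    Returned is the quadratic form ``(t-mu)' Sigma^+ (t-mu)`` and its
    chi-square p-value with df = rank(Sigma).  Case weights are 0/1 subset
    indicators.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if weights is not None:
        keep = np.asarray(weights) > 0
        x, labels = x[keep], labels[keep]
    n = len(x)
    classes, H = _class_indicators(labels)
    if len(classes) < 2:
        raise ValueError("no association testable: a single label class present")
    pi = H.mean(axis=0)
    t = x @ H
    mu = x.sum() * pi
    Vh = np.diag(pi) - np.outer(pi, pi)
    factor = (n * (x**2).sum() - x.sum() ** 2) / (n - 1)
    Sigma = Vh * factor
    d = t - mu
    if not np.any(np.abs(Sigma) > 0):
        return 0.0, 1.0
    rank = np.linalg.matrix_rank(Sigma)
    stat = float(d @ np.linalg.pinv(Sigma, hermitian=True) @ d)
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=rank))


def select_split_variable(
    table: ExpressionTable,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
) -> str | None:
    """Bonferroni-adjusted marker selection; ``None`` (STOP) if nothing rejects.

    Ties on the adjusted p-value resolve to the first marker in table
    order, deterministically.
    """
    r = table.n_markers
    adjusted = np.empty(r)
    for k in range(r):
        _, p = association_test(table.values[:, k], labels, weights)
        adjusted[k] = min(p * r, 1.0)
    best = int(np.argmin(adjusted))
    if adjusted[best] > alpha:
        return STOP
    return table.marker_names[best]


def best_binary_split(
    x: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    minbucket: int = 1,
) -> tuple[SplitProfile, float]:
    """Optimal split point on a selected marker.

    For each admissible candidate ``v`` (at least ``minbucket`` cells on
    each side of ``{<= v, > v}``), the two-sample linear statistic
    ``t_j = sum_{x_i <= v} 1(y_i = j)`` is standardized component-wise by
    its permutation mean and variance, and the candidate maximizing the
    maximum absolute standardized component wins; ties go to the smallest
    candidate.  The returned split point is the midpoint between the
    winning candidate and the next larger observed value — the gate is
    drawn through the middle of the empty interval, where a sorter would
    place it, which also keeps bootstrap split-point ranges centered
    rather than pinned to an extreme order statistic of the left group.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if weights is not None:
        keep = np.asarray(weights) > 0
        x, labels = x[keep], labels[keep]
    n = len(x)
    if n < 2 * minbucket:
        raise ValueError("node unsplittable: fewer than 2*minbucket cells")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    classes, H = _class_indicators(labels[order])
    pi = H.mean(axis=0)
    Vh_diag = pi * (1.0 - pi)
    cumH = np.cumsum(H, axis=0)

    # last sorted position of each distinct value; cutting after position i
    # puts i+1 cells in the left group
    last_of_value = np.flatnonzero(np.r_[xs[1:] != xs[:-1], True])
    n_left = last_of_value + 1
    admissible = (n_left >= minbucket) & (n - n_left >= minbucket)
    if not np.any(admissible):
        raise ValueError("node unsplittable: no candidate satisfies minbucket")
    pos = last_of_value[admissible]
    nA = n_left[admissible].astype(float)

    t = cumH[pos]  # (n_cand, q)
    mu = nA[:, None] * pi[None, :]
    var = Vh_diag[None, :] * (nA * (n - nA) / (n - 1))[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (t - mu) / np.sqrt(var), 0.0)
    stats = np.abs(z).max(axis=1)
    best = int(np.argmax(stats))  # argmax ties -> first (= smallest candidate)
    profile = SplitProfile(candidates=xs[pos], statistics=stats, argmax=best)
    left_max = xs[pos][best]
    right_min = xs[pos[best] + 1]
    return profile, float((left_max + right_min) / 2.0)


def default_minbucket(n: int) -> int:
    """Minimum daughter-node size: max(20, 1% of the training cells)."""
    return max(20, math.ceil(0.01 * n))


def grow_tree(
    table: ExpressionTable,
    labels: np.ndarray,
    alpha: float = 0.05,
    minbucket: int | None = None,
    max_height: int | None = None,
) -> GatingTree:
    """Grow the binary gating tree by recursive variable selection/splitting.

    Recursion at a node stops when it is label-pure, smaller than
    ``2*minbucket``, at depth ``max_height``, when no marker passes the
    Bonferroni-adjusted association test at ``alpha``, or when no
    admissible split exists.  Leaves are annotated with their composition,
    dominant label (ties to the lower label id) and purity.
    """
    labels = np.asarray(labels)
    n = table.n_cells
    if minbucket is None:
        minbucket = default_minbucket(n)
    tree = GatingTree()
    counter = iter(range(10**9))

    def make_leaf(idx: np.ndarray) -> int:
        nid = next(counter)
        classes, counts = np.unique(labels[idx], return_counts=True)
        dom = int(classes[np.argmax(counts)])  # argmax ties -> lower label id
        tree.nodes[nid] = GatingNode(
            id=nid,
            kind="leaf",
            composition={int(c): int(k) for c, k in zip(classes, counts)},
            dominant=dom,
            purity=float(counts.max() / counts.sum()),
            size=len(idx),
        )
        return nid

    def build(idx: np.ndarray, depth: int) -> int:
        node_labels = labels[idx]
        if (
            len(np.unique(node_labels)) < 2
            or len(idx) < 2 * minbucket
            or (max_height is not None and depth >= max_height)
        ):
            return make_leaf(idx)
        sub = table.subset_events(idx)
        marker = select_split_variable(sub, node_labels, alpha=alpha)
        if marker is STOP:
            return make_leaf(idx)
        xcol = sub.marker(marker)
        try:
            _, c = best_binary_split(xcol, node_labels, minbucket=minbucket)
        except ValueError:
            return make_leaf(idx)
        nid = next(counter)
        _, p = association_test(xcol, node_labels)
        left = build(idx[xcol <= c], depth + 1)
        right = build(idx[xcol > c], depth + 1)
        tree.nodes[nid] = GatingNode(
            id=nid,
            kind="internal",
            marker=marker,
            split_point=c,
            p_value=min(p * table.n_markers, 1.0),
            children=(left, right),
            size=len(idx),
        )
        return nid

    tree.root = build(np.arange(n), 0)
    return tree


def apply_tree(tree: GatingTree, table: ExpressionTable) -> np.ndarray:
    """Route every cell root-to-leaf; returns the leaf id per cell.

    A cell whose marker value equals the split point goes left (the ``<=``
    convention).  Raises ``KeyError`` naming any marker the table lacks.
    """
    for m in tree.markers_used:
        table.marker_index(m)  # raises KeyError with available markers
    n = table.n_cells
    assignment = np.full(n, tree.root)
    active = [nid for nid in (tree.root,) if tree.nodes[nid].kind == "internal"]
    while active:
        nid = active.pop()
        node = tree.nodes[nid]
        here = assignment == nid
        vals = table.marker(node.marker)
        left, right = node.children
        assignment[here & (vals <= node.split_point)] = left
        assignment[here & (vals > node.split_point)] = right
        for child in (left, right):
            if tree.nodes[child].kind == "internal":
                active.append(child)
    return assignment
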