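"""Distance-based tree reconstruction and topology comparison.

Trees are :class:`dendropy.Tree` objects throughout.  The builders here are
deterministic: ties in the agglomeration criteria are broken by the smallest
(row, column) index pair of the current working matrix, and negative branch
lengths (which neighbor joining can produce on non-additive input) are
clamped to zero so serialized trees stay viewer-friendly.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "nj",
    "upgma",
    "midpoint_root",
    "rf_distance",
    "same_topology",
    "leaf_labels",
    "bipartitions",
]

logger = logging.getLogger(__name__)


def _refuse_undefined(m: DistanceMatrix) -> None:
    if m.has_undefined:
        raise ValueError(
            f"matrix contains undefined (saturated) entries: {m.undefined_pairs}; "
            "refusing to build a tree"
        )


def _leaf_nodes(labels, tns: dendropy.TaxonNamespace) -> list[dendropy.Node]:
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=tns.require_taxon(label=label))
        nodes.append(node)
    return nodes


def _argmin_upper(mat: np.ndarray) -> tuple[int, int]:
    """Index pair (i < j) of the minimum over the strict upper triangle.

    ``np.argmin`` scans row-major, so the first minimum encountered is the
    lexicographically smallest (i, j) — the documented tie-break.
    """
    n = mat.shape[0]
    masked = np.where(np.triu(np.ones((n, n), dtype=bool), k=1), mat, np.inf)
    flat = int(np.argmin(masked))
    return divmod(flat, n)


def nj(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q-criterion.

    Returns an unrooted tree (trifurcating seed node).  Exact on additive
    matrices.  Requires at least 3 taxa and no undefined entries.
    """
    _refuse_undefined(m)
    if m.n < 3:
        raise ValueError("NJ requires >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(m.labels, tns)
    D = m.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        i, j = _argmin_upper(Q)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        # the merged cluster takes slot i; slot j is dropped
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    root = dendropy.Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def upgma(m: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) clustering; rooted, ultrametric output.

    Cluster heights are half the average inter-cluster distance; new
    distances are size-weighted averages.
    """
    _refuse_undefined(m)
    if m.n < 2:
        raise ValueError("UPGMA requires >= 2 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(m.labels, tns)
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    D = m.values.astype(float).copy()

    while len(nodes) > 1:
        i, j = _argmin_upper(D)
        height = D[i, j] / 2.0
        parent = dendropy.Node()
        for child, h in ((nodes[i], heights[i]), (nodes[j], heights[j])):
            parent.add_child(child)
            child.edge.length = max(height - h, 0.0)
        ni, nj_ = sizes[i], sizes[j]
        d_new = (ni * D[i, :] + nj_ * D[j, :]) / (ni + nj_)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        heights[i] = height
        sizes[i] = ni + nj_
        del nodes[j], heights[j], sizes[j]

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of ``tree`` at the midpoint of its longest leaf-to-leaf path."""
    rooted = tree.clone(depth=1)
    total = sum(e.length or 0.0 for e in rooted.preorder_edge_iter())
    if total == 0.0:
        logger.warning("tree has zero total length; midpoint rooting is arbitrary")
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each written as the leaf-label set
    on the side *not* containing the lexicographically smallest label."""
    labels = sorted(leaf_labels(tree))
    index = {lab: 1 << k for k, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    masks = _split_masks(tree, index, full)
    bit_to_label = {bit: lab for lab, bit in index.items()}
    out = set()
    for mask in masks:
        members = frozenset(
            bit_to_label[1 << k] for k in range(len(labels)) if mask >> k & 1
        )
        out.add(members)
    return frozenset(out)


def _split_masks(tree: dendropy.Tree, index: dict[str, int], full: int) -> set[int]:
    n = len(index)
    masks: dict[int, int] = {}
    out: set[int] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = index[node.taxon.label]
        else:
            mask = 0
            for child in node.child_nodes():
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent_node is None:
            continue
        canon = mask ^ full if mask & 1 else mask
        size = canon.bit_count()
        if 2 <= size <= n - 2:
            out.add(canon)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric difference of the
    non-trivial bipartition sets).  Both trees must share a leaf label set."""
    labels1, labels2 = leaf_labels(t1), leaf_labels(t2)
    if labels1 != labels2:
        raise ValueError(
            f"trees have different leaf sets: {sorted(labels1 ^ labels2)}"
        )
    index = {lab: 1 << k for k, lab in enumerate(sorted(labels1))}
    full = (1 << len(index)) - 1
    return len(_split_masks(t1, index, full) ^ _split_masks(t2, index, full))


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """True when the unrooted RF distance is zero."""
    return rf_distance(t1, t2) == 0
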