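"""Shared phylogenetic-tree utilities built on dendropy."""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more newick trees from a file."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_depths(tree: dendropy.Tree) -> np.ndarray:
    """Root-to-tip distances in leaf iteration order."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return np.array([leaf.root_distance for leaf in tree.leaf_node_iter()])


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    d = tree_depths(tree)
    return bool(np.ptp(d) <= tol)


def tip_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths.

    Returns (C, labels) with C[i, j] = depth of the MRCA of tips i and j
    and C[i, i] = root-to-tip distance.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    # Accumulate per-edge: each edge contributes its length to all pairs of
    # tips descending from its child node.
    index = {lf: i for i, lf in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tip_idx = [index[node]]
        else:
            node._tip_idx = [i for ch in node.child_nodes() for i in ch._tip_idx]
        edge_len = node.edge.length or 0.0
        if node.parent_node is not None and edge_len:
            idx = np.array(node._tip_idx)
            C[np.ix_(idx, idx)] += edge_len
    for node in tree.postorder_node_iter():
        del node._tip_idx
    return C, labels


def scale_to_unit_depth(tree: dendropy.Tree) -> dendropy.Tree:
    """Rescale all branch lengths so the maximum root-to-tip distance is 1."""
    depth = float(tree_depths(tree).max())
    if depth <= 0:
        raise ValueError("tree has zero depth")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree
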