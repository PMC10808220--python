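"""Recursive feature selection + sub-clustering with principled stop rules.

Iterative sub-clustering pipelines re-run feature selection and clustering
inside each discovered cluster. Without a selector that can report "no
features here", this recursion runs to completion — nearly every cell ends
up its own cluster. The harness makes both behaviors observable: it recurses
until (a) the selector returns no features, (b) the clusterer finds a single
cluster, or (c) the split would produce a group at or below the minimum
cluster size. An engineering ``max_depth`` guard caps runaway recursion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["RecursionNode", "recursive_subcluster", "tree_stats", "all_genes_selector"]


@dataclass
class RecursionNode:
    """One node of the recursion tree.

    ``path`` is the sequence of cluster labels from the root (empty at the
    root, whose depth is 0). ``stop_reason`` is one of ``no_features``,
    ``single_cluster``, ``min_size``, ``max_depth`` or ``split`` (internal
    node). Leaf cell sets partition the root cell set.
    """

    path: tuple[int, ...]
    cell_ids: np.ndarray
    depth: int
    n_features_selected: int = 0
    stop_reason: str = "split"
    children: list["RecursionNode"] = field(default_factory=list)

    def leaves(self) -> list["RecursionNode"]:
        if not self.children:
            return [self]
        out: list[RecursionNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "path": list(self.path),
            "cell_ids": [int(c) for c in self.cell_ids],
            "depth": self.depth,
            "n_features_selected": self.n_features_selected,
            "stop_reason": self.stop_reason,
            "children": [c.to_dict() for c in self.children],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def all_genes_selector(expr: np.ndarray) -> np.ndarray:
    """Degenerate selector that keeps every gene.

    Models feature-selection methods with a fixed number of "discoveries":
    they never return an empty set, so recursion only halts on cluster-size
    grounds — the recursion-to-completion failure mode.
    """
    return np.ones(expr.shape[0], dtype=bool)


def recursive_subcluster(
    expr: np.ndarray,
    selector: Callable[[np.ndarray], np.ndarray],
    clusterer: Callable[[np.ndarray, int], np.ndarray],
    min_cluster_size: int = 5,
    max_depth: int = 20,
    seed: int = 0,
    block_whole_split: bool = True,
) -> RecursionNode:
    """Recursively select features and sub-cluster.

    Parameters
    ----------
    expr
        Genes x cells matrix (normalized).
    selector
        Maps a genes x cells matrix to a boolean gene mask.
    clusterer
        Maps (selected-features matrix, seed) to integer labels per cell.
    min_cluster_size
        A split producing any group of at most this many cells stops the
        recursion (``block_whole_split=True``, the conservative default) or
        only closes the offending children (``False``).
    max_depth
        Hard depth cap; nodes closed here carry ``stop_reason="max_depth"``.
    """
    expr = np.asarray(expr)
    root_cells = np.arange(expr.shape[1])
    return _recurse(
        expr, root_cells, (), 0, selector, clusterer, min_cluster_size,
        max_depth, seed, block_whole_split,
    )


def _recurse(
    expr, cells, path, depth, selector, clusterer, min_size, max_depth, seed,
    block_whole_split,
) -> RecursionNode:
    node = RecursionNode(path=path, cell_ids=cells, depth=depth)
    if len(cells) <= min_size:
        node.stop_reason = "min_size"
        return node
    if depth >= max_depth:
        warnings.warn(f"max_depth={max_depth} reached at path {path}")
        node.stop_reason = "max_depth"
        return node
    sub = expr[:, cells]
    mask = np.asarray(selector(sub), dtype=bool)
    node.n_features_selected = int(mask.sum())
    if node.n_features_selected == 0:
        node.stop_reason = "no_features"
        return node
    labels = np.asarray(clusterer(sub[mask], seed))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        node.stop_reason = "single_cluster"
        return node
    sizes = np.array([(labels == u).sum() for u in uniq])
    if block_whole_split and np.any(sizes <= min_size):
        node.stop_reason = "min_size"
        return node
    node.stop_reason = "split"
    for u in uniq:
        child_cells = cells[labels == u]
        child = _recurse(
            expr, child_cells, path + (int(u),), depth + 1, selector,
            clusterer, min_size, max_depth, seed, block_whole_split,
        )
        node.children.append(child)
    return node


def tree_stats(root: RecursionNode) -> dict:
    """Leaf count, per-leaf depths and mean leaf depth of a recursion tree."""
    leaves = root.leaves()
    depths = np.array([leaf.depth for leaf in leaves])
    return {
        "n_leaves": len(leaves),
        "leaf_depths": depths,
        "mean_leaf_depth": float(depths.mean()),
        "stop_reasons": {leaf.stop_reason for leaf in leaves},
    }
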