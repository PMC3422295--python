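"""Shared hierarchical-clustering helpers: correlation distances,
average linkage, and Newick export of the resulting trees."""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


def correlation_distance(rows: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Pairwise 1 − correlation between the rows of a matrix.

    ``method`` is "pearson" or "spearman" (mid-rank Pearson).  Distances
    are clipped into [0, 2] against rounding noise.
    """
    if method == "spearman":
        rows = np.apply_along_axis(rankdata, 1, rows)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method}")
    corr = np.corrcoef(rows)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def average_linkage(dist: np.ndarray) -> np.ndarray:
    # force exact symmetry before condensing; corrcoef leaves ~1e-16 skew
    dist = (dist + dist.T) / 2.0
    return hierarchy.average(squareform(dist, checks=False))


def leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    return [labels[i] for i in hierarchy.leaves_list(linkage)]


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage as a Newick string with branch lengths.

    Branch lengths are differences of successive merge heights, the usual
    convention for ultrametric average-linkage trees.
    """
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
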