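"""Average-linkage hierarchical clustering shared by several stages.

Labels are sorted lexicographically before linkage so that distance ties
resolve the same way on every platform; dendrograms serialize to Newick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

__all__ = ["average_linkage_from_distance", "cut_to_k", "linkage_to_newick",
           "cluster_rows_and_columns"]


def average_linkage_from_distance(dist: np.ndarray) -> np.ndarray:
    """Average-linkage tree from a square symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="average")


def cut_to_k(z: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into exactly k flat clusters (labels 1..k)."""
    n_leaves = z.shape[0] + 1
    if k > n_leaves:
        raise ValueError(f"cannot cut {n_leaves} leaves into {k} clusters")
    return fcluster(z, t=k, criterion="maxclust")


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree to a Newick string with branch lengths."""
    tree = to_tree(z, rd=False)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_rows_and_columns(
    frame: pd.DataFrame,
) -> tuple[pd.DataFrame, str, str]:
    """Cluster rows and columns of a matrix independently (HCL style).

    Average linkage on Euclidean distance, the convention used for NES and
    time-course heatmaps.  Returns the reordered matrix plus row and column
    dendrograms as Newick strings.  A single row or column keeps identity
    ordering with a trivial tree.
    """
    frame = frame.sort_index(axis=0).sort_index(axis=1)

    def one_axis(mat: pd.DataFrame) -> tuple[list, str]:
        labels = [str(x) for x in mat.index]
        if len(labels) < 2:
            return list(mat.index), (f"{labels[0]};" if labels else ";")
        z = linkage(pdist(mat.to_numpy(), metric="euclidean"), method="average")
        order = leaves_list(z)
        return [mat.index[i] for i in order], linkage_to_newick(z, labels)

    row_order, row_newick = one_axis(frame)
    col_order, col_newick = one_axis(frame.T)
    return frame.loc[row_order, col_order], row_newick, col_newick
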