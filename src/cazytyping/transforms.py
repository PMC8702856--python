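"""Preprocessing and unsupervised structure: log10(x+1), Z-score
standardization, Spearman-distance hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

Linkage = Literal["single", "complete", "average", "ward"]


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(x + 1); zeros map to zero.  Cells must be >= 0."""
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise ValueError("log transform requires non-negative abundances")
    return pd.DataFrame(np.log10(values + 1.0), index=matrix.index, columns=matrix.columns)


@dataclass
class StandardizedMatrix:
    """Column-wise Z scores with the stored (mu, sigma) used per column.

    Zero-variance columns cannot be standardized; their z values are set to
    zero and the column names recorded in ``degenerate``.
    """

    values: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    ddof: int = 1
    degenerate: list = field(default_factory=list)

    def drop_degenerate(self) -> pd.DataFrame:
        return self.values.drop(columns=self.degenerate)


def z_standardize(matrix: pd.DataFrame, ddof: int = 1) -> StandardizedMatrix:
    """Standardize each column to mean 0, sd 1: z = (x - mu) / sigma.

    ``ddof`` selects the sd denominator (n - ddof); the default is the
    sample sd.  Constant columns are flagged and set to all-zero rather
    than erroring, so invariant families survive to the heatmap stage.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = matrix.mean(axis=0)
    sigma = matrix.std(axis=0, ddof=ddof)
    degenerate = list(sigma.index[sigma == 0])
    safe_sigma = sigma.replace(0, 1.0)
    z = (matrix - mu) / safe_sigma
    z[degenerate] = 0.0
    return StandardizedMatrix(values=z, mu=mu, sigma=sigma, ddof=ddof, degenerate=degenerate)


def spearman_distance(matrix: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Pairwise Spearman distance d = 1 - rho between rows (axis=0) or
    columns (axis=1); range [0, 2], zero diagonal.  Ties get midranks.

    A constant vector has undefined rank correlation and raises, naming it.
    """
    data = matrix if axis == 0 else matrix.T
    labels = data.index
    values = data.to_numpy(float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    constant = [str(labels[i]) for i in range(values.shape[0]) if np.ptp(values[i]) == 0]
    if constant:
        raise ValueError(f"Spearman correlation undefined for constant vectors: {constant}")
    ranks = np.apply_along_axis(rankdata, 1, values)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    dist = 1.0 - np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled leaves.

    ``linkage_matrix`` is in scipy's (n-1) x 4 format; heights are
    non-decreasing along root paths for the monotone linkages used here.
    """

    linkage_matrix: np.ndarray
    leaves: list
    method: str
    distance: str = "spearman"

    def cut(self, k: int) -> pd.Series:
        """Cluster membership (1..k) when cutting into k flat clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def to_newick(self) -> str:
        """Serialize as a Newick string; branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else node.dist
            length = max(parent_height - height, 0.0)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.10g}"
            children = ",".join(
                render(c, height) for c in (node.get_left(), node.get_right())
            )
            return f"({children}):{length:.10g}"

        if tree.is_leaf():
            return f"{self.leaves[tree.id]};"
        children = ",".join(
            render(c, tree.dist) for c in (tree.get_left(), tree.get_right())
        )
        return f"({children});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def hierarchical_cluster(distance: pd.DataFrame, method: Linkage = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    Deterministic: among equally distant pairs scipy merges the smallest
    index pair first, so input order fixes the tree.
    """
    values = distance.to_numpy(float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = values.shape[0]
    condensed = values[np.triu_indices(n, k=1)]
    z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage_matrix=z, leaves=list(distance.index), method=method)
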