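"""Cross-epigenome similarity of one chromatin state.

The territory of one state (typically the strong enhancer state) is
extracted from each sample's segmentation as a merged interval set; all
pairs are compared by bp-level Jaccard similarity; samples are then
clustered hierarchically on the Euclidean distance between rows of the
similarity matrix (each sample's profile of similarities to every
sample).  The alternative metric d = 1 - J is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .intervals import IntervalSet, jaccard
from .segmentation import Segmentation

__all__ = [
    "SimilarityMatrix",
    "ClusterResult",
    "state_intervals",
    "pairwise_similarity",
    "cluster_samples",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jaccard similarities between named samples."""

    sample_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_names = tuple(self.sample_names)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with sample names")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("similarities must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.sample_names), columns=list(self.sample_names)
        )


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples.

    ``linkage_matrix`` is the scipy linkage encoding; ``leaf_order`` the
    dendrogram leaf order; ``newick`` a Newick serialization with merge
    heights as branch lengths.
    """

    sample_names: tuple[str, ...]
    linkage_matrix: np.ndarray
    leaf_order: tuple[str, ...]
    newick: str

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels at a cut into ``n_clusters`` groups."""
        flat = hierarchy.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.sample_names, (int(x) for x in flat)))


def state_intervals(seg: Segmentation, state: int | str) -> IntervalSet:
    """Merged intervals covering exactly the bins assigned one state."""
    return seg.state_intervals(state)


def pairwise_similarity(interval_sets: dict[str, IntervalSet]) -> SimilarityMatrix:
    """All-pairs bp Jaccard similarity.

    The diagonal is 1 for non-empty samples; an empty sample has
    similarity 0 to everything including itself (with a warning), which
    keeps the matrix finite for sparse states.
    """
    names = list(interval_sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate sample names")
    if len(names) < 2:
        raise ValueError("need at least 2 samples")
    empties = [n for n in names if interval_sets[n].covered_bp() == 0]
    if empties:
        warnings.warn(f"samples with empty state territory: {empties}")
    n = len(names)
    vals = np.zeros((n, n))
    for i in range(n):
        if names[i] not in empties:
            vals[i, i] = 1.0
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jaccard(
                interval_sets[names[i]], interval_sets[names[j]]
            )
    return SimilarityMatrix(tuple(names), vals)


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_samples(
    sim: SimilarityMatrix,
    linkage: str = "average",
    metric: str = "profile",
) -> ClusterResult:
    """Hierarchical clustering of samples from the similarity matrix.

    ``metric="profile"`` (default) converts similarities to distances as
    the Euclidean distance between similarity-matrix rows, so two samples
    with identical similarity profiles are at distance 0 even if their
    interval sets differ.  ``metric="one_minus"`` uses d = 1 - J instead.
    """
    if np.isnan(sim.values).any():
        raise ValueError("similarity matrix contains NaN")
    if metric == "profile":
        dist = pdist(sim.values, metric="euclidean")
    elif metric == "one_minus":
        dist = squareform(1.0 - sim.values, checks=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(dist, method=linkage)
    dn = hierarchy.dendrogram(Z, no_plot=True)
    leaf_order = tuple(sim.sample_names[i] for i in dn["leaves"])
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, list(sim.sample_names)) + ";"
    return ClusterResult(sim.sample_names, Z, leaf_order, newick)
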