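"""Clustering of sequences in motif-feature space.

Four modes, mirroring common practice for genome-composition vectors:

* **k-means** — Lloyd's algorithm with k-means++ seeding and 10 restarts,
  for when the number of groups K is known.
* **PCA + k-means** — max-abs normalize, project onto the leading principal
  components, then k-means in the reduced space; the 2-D embedding is kept
  for scatter plots.
* **mean shift** — flat-kernel mode seeking with an automatically estimated
  bandwidth (quantile 0.3 nearest-neighbour rule), so the number of clusters
  emerges from the kernel density estimate rather than being user-set.
* **clustermap ordering** — agglomerative hierarchical clustering of rows
  and columns; with single linkage the merge heights are exactly the sorted
  edge weights of the minimum spanning tree of the distance graph, which is
  the classical MST view of this method. Average linkage is the default, as
  in standard clustered-heatmap practice.

The iterative algorithms are backed by scikit-learn; hierarchical linkage by
scipy. All stochastic entry points take an explicit seed (default 0) and
record their parameters on the result for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans, MeanShift, estimate_bandwidth
from sklearn.decomposition import PCA

from .errors import ParameterError
from .feature_matrix import FeatureMatrix, maxabs_normalize

import logging

logger = logging.getLogger(__name__)

METHODS = ("kmeans", "pca_kmeans", "meanshift")
LINKAGES = ("single", "average")


@dataclass
class ClusteringResult:
    """Labels, centers and parameters of one clustering run."""

    method: str
    labels: np.ndarray            # one 0-based integer label per input row
    n_clusters: int
    centers: np.ndarray           # cluster centers in the clustered space
    row_ids: list[str]
    embedding: np.ndarray | None = None   # n×2 PCA coordinates (pca_kmeans)
    explained_variance: np.ndarray | None = None
    params: dict = field(default_factory=dict)


@dataclass
class ClusterMapResult:
    """Row/column dendrogram orders and merge records of a clustermap run."""

    row_order: np.ndarray         # permutation of row indices
    col_order: np.ndarray         # permutation of column indices
    row_merges: np.ndarray        # scipy linkage matrix (pair, height, size)
    col_merges: np.ndarray
    metric: str
    linkage: str
    row_ids: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)


def kmeans_cluster(matrix: FeatureMatrix, k: int, seed: int = 0) -> ClusteringResult:
    """K-means with k-means++ seeding, 10 restarts, best inertia kept."""
    n = matrix.shape[0]
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of sequences ({n})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(matrix.values)
    return ClusteringResult(
        method="kmeans", labels=km.labels_.astype(int), n_clusters=k,
        centers=km.cluster_centers_, row_ids=matrix.row_ids,
        params={"k": k, "seed": seed, "n_init": 10},
    )


def pca_project(matrix: FeatureMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Project rows onto the leading principal components.

    Columns are mean-centered; components are orthonormal right singular
    vectors with a deterministic sign convention (the largest-magnitude
    loading of each component is positive). Returns the embedding and the
    explained-variance fractions (non-increasing, summing to <= 1).
    """
    n, p = matrix.shape
    if not 1 <= n_components <= min(n, p):
        raise ParameterError(
            f"n_components must be in [1, {min(n, p)}], got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(matrix.values)
    # Fix signs: flip any component whose largest-|loading| entry is negative.
    for j, comp in enumerate(pca.components_):
        i = int(np.argmax(np.abs(comp)))
        if comp[i] < 0:
            emb[:, j] *= -1.0
    return emb, pca.explained_variance_ratio_


def pca_kmeans(matrix: FeatureMatrix, k: int, n_components: int = 2,
               seed: int = 0) -> ClusteringResult:
    """Max-abs normalize, PCA-project, then k-means on the embedding."""
    if not matrix.normalized:
        matrix = maxabs_normalize(matrix)
    n_components = min(n_components, min(matrix.shape))
    emb, evr = pca_project(matrix, n_components)
    from .feature_matrix import FeatureMatrix as _FM
    import pandas as pd
    emb_matrix = _FM(
        df=pd.DataFrame(emb, index=matrix.row_ids,
                        columns=[f"PC{i+1}" for i in range(emb.shape[1])]),
        basis=matrix.basis, normalized=True)
    res = kmeans_cluster(emb_matrix, k, seed=seed)
    return ClusteringResult(
        method="pca_kmeans", labels=res.labels, n_clusters=k,
        centers=res.centers, row_ids=matrix.row_ids, embedding=emb,
        explained_variance=evr,
        params={"k": k, "n_components": n_components, "seed": seed},
    )


def meanshift_cluster(matrix: FeatureMatrix, bandwidth: float | None = None,
                      seed: int = 0) -> ClusteringResult:
    """Flat-kernel mean shift; the cluster count emerges from the data.

    When ``bandwidth`` is not given it is estimated as the mean distance to
    each point's (0.3·n)-th nearest neighbour (quantile rule). A zero
    estimate (all points identical) yields a single cluster with a warning.
    """
    X = matrix.values
    if X.shape[0] == 0:
        raise ParameterError("matrix has no rows")
    if bandwidth is not None and bandwidth <= 0:
        raise ParameterError(f"bandwidth must be > 0, got {bandwidth}")
    bw = bandwidth
    if bw is None:
        bw = float(estimate_bandwidth(X, quantile=0.3, random_state=seed))
        if bw <= 0.0:
            logger.warning("estimated bandwidth is 0 (identical points); "
                           "returning a single cluster")
            labels = np.zeros(X.shape[0], dtype=int)
            return ClusteringResult(
                method="meanshift", labels=labels, n_clusters=1,
                centers=X.mean(axis=0, keepdims=True), row_ids=matrix.row_ids,
                params={"bandwidth": 0.0, "seed": seed})
    ms = MeanShift(bandwidth=bw, max_iter=300).fit(X)
    labels = ms.labels_.astype(int)
    return ClusteringResult(
        method="meanshift", labels=labels,
        n_clusters=int(labels.max()) + 1, centers=ms.cluster_centers_,
        row_ids=matrix.row_ids,
        params={"bandwidth": float(bw), "seed": seed,
                "bandwidth_estimated": bandwidth is None},
    )


def clustermap(matrix: FeatureMatrix, metric: str = "euclidean",
               linkage_method: str = "average") -> ClusterMapResult:
    """Hierarchical row and column ordering for a clustered heatmap.

    Agglomerative clustering with the stated metric and linkage on rows and
    on columns; leaves ordered by the standard dendrogram traversal with
    optimal ordering disabled, so results are deterministic. Identical rows
    merge first at height 0 and end up adjacent.
    """
    if linkage_method not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}, got {linkage_method!r}")
    n, p = matrix.shape
    if n < 2 or p < 2:
        raise ParameterError("clustermap requires at least 2 rows and 2 columns")
    X = matrix.values
    if not np.isfinite(X).all():
        raise ParameterError("matrix contains non-finite entries")
    row_z = linkage(pdist(X, metric=metric), method=linkage_method)
    col_z = linkage(pdist(X.T, metric=metric), method=linkage_method)
    return ClusterMapResult(
        row_order=leaves_list(row_z), col_order=leaves_list(col_z),
        row_merges=row_z, col_merges=col_z,
        metric=metric, linkage=linkage_method,
        row_ids=matrix.row_ids, col_names=matrix.col_names,
    )


def merges_to_newick(merges: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string for external viewers."""

    def render(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id].replace(" ", "_")
        left, right = node.get_left(), node.get_right()
        bl = node.dist - left.dist
        br = node.dist - right.dist
        return f"({render(left)}:{bl:.10g},{render(right)}:{br:.10g})"

    tree = to_tree(merges)
    return render(tree) + ";"
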