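"""Cell clustering on selected features.

The primary method is *locally weighted Louvain*: Louvain community
detection on a locally thresholded, row-normalized cell-cell similarity
graph derived from cell-cell Spearman correlations. K-means with elbow or
silhouette model selection and affinity propagation with SD-based cluster
merging are provided as the alternative clusterers used in benchmarking.

All methods take a genes x cells matrix already restricted to the selected
features and return 0-based contiguous integer labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from networkx.algorithms.community import louvain_communities
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata
from sklearn.cluster import AffinityPropagation, KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

__all__ = [
    "WeightedAdjacency",
    "ClusterAssignment",
    "locally_weighted_graph",
    "louvain_cluster",
    "kmeans_elbow",
    "kmeans_silhouette",
    "ap_merge_cluster",
]

log = logging.getLogger(__name__)

#: locally weighted graph keeps at most min(5% of cells, this many) neighbors
TOP_K_NEIGHBORS = 200
LOCAL_PERCENTILE = 95.0


@dataclass
class WeightedAdjacency:
    """Row-max-normalized, locally thresholded cell-cell weight matrix."""

    weights: np.ndarray
    percentile: float = LOCAL_PERCENTILE
    top_k: int = TOP_K_NEIGHBORS


@dataclass
class ClusterAssignment:
    """Cluster label per cell, 0-based contiguous."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous integers starting at 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first appearance (deterministic)."""
    _, out = np.unique(labels, return_inverse=True)
    first = {}
    remap = np.empty(out.max() + 1, dtype=np.int64)
    nxt = 0
    for v in out:
        if v not in first:
            first[v] = nxt
            nxt += 1
    for v, r in first.items():
        remap[v] = r
    return remap[out]


def _cell_spearman(expr_selected: np.ndarray) -> np.ndarray:
    """Cell-cell Spearman correlation matrix (cells as observations)."""
    # rank each cell's gene vector (mid-ranks), then Pearson across cells
    cell_ranks = rankdata(expr_selected, method="average", axis=0)
    z = cell_ranks - cell_ranks.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z /= sd
    return (z.T @ z) / expr_selected.shape[0]


def locally_weighted_graph(expr_selected: np.ndarray) -> WeightedAdjacency:
    """Build the locally weighted cell-cell adjacency matrix.

    Steps: (1) cell-cell Spearman correlation matrix S; (2) similarity
    D = 1 / squared-Euclidean-distance between rows of S, divided by
    sqrt(n_cells), self-entries zero (exact duplicates get the row's largest
    finite similarity); (3) per row subtract the 95th-percentile value or the
    200th-largest value, whichever removes more edges, and clamp negatives to
    zero — each cell keeps at most min(5% of cells, 200) neighbors; (4) divide
    each nonzero row by its maximum.
    """
    expr_selected = np.asarray(expr_selected, dtype=np.float64)
    n_cells = expr_selected.shape[1]
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    S = _cell_spearman(expr_selected)
    d2 = squareform(pdist(S, metric="sqeuclidean"))
    with np.errstate(divide="ignore"):
        D = 1.0 / d2
    D /= np.sqrt(n_cells)
    np.fill_diagonal(D, 0.0)
    # exact duplicate cells: zero distance -> substitute the row max finite value
    for i, j in zip(*np.nonzero(np.isinf(D))):
        row = D[i]
        finite = row[np.isfinite(row)]
        D[i, j] = finite.max() if finite.size else 1.0
    L = np.empty_like(D)
    off = ~np.eye(n_cells, dtype=bool)
    for i in range(n_cells):
        vals = D[i][off[i]]
        thr_pct = np.percentile(vals, LOCAL_PERCENTILE)
        if vals.size >= TOP_K_NEIGHBORS:
            thr_top = np.partition(vals, -TOP_K_NEIGHBORS)[-TOP_K_NEIGHBORS]
        else:
            thr_top = -np.inf
        thr = max(thr_pct, thr_top)  # higher threshold -> fewer connections
        L[i] = np.maximum(D[i] - thr, 0.0)
        L[i, i] = 0.0
        m = L[i].max()
        if m > 0:
            L[i] /= m
    return WeightedAdjacency(weights=L)


def louvain_cluster(adj: WeightedAdjacency | np.ndarray, seed: int = 0) -> ClusterAssignment:
    """Weighted Louvain modularity communities on the adjacency matrix.

    The (possibly asymmetric) local adjacency is symmetrized with the
    elementwise maximum — an edge survives if either endpoint kept it as a
    neighbor — before modularity maximization. Deterministic under the seed.
    """
    W = adj.weights if isinstance(adj, WeightedAdjacency) else np.asarray(adj)
    if W.size == 0:
        raise ValueError("empty adjacency")
    sym = np.maximum(W, W.T)
    G = nx.from_numpy_array(sym)
    communities = louvain_communities(G, weight="weight", seed=seed)
    labels = np.empty(W.shape[0], dtype=np.int64)
    for c, members in enumerate(communities):
        labels[list(members)] = c
    return ClusterAssignment(
        labels=_contiguous(labels), method="louvain", params={"seed": seed}
    )


def _minmax_genes(expr_selected: np.ndarray) -> np.ndarray:
    """Min-max scale each gene to [0, 1]; cells become the samples."""
    x = np.asarray(expr_selected, dtype=np.float64)
    lo = x.min(axis=1, keepdims=True)
    rng_ = x.max(axis=1, keepdims=True) - lo
    rng_[rng_ == 0] = 1.0
    return ((x - lo) / rng_).T  # cells x genes


def kmeans_elbow(
    expr_selected: np.ndarray, k_max: int = 15, seed: int = 0
) -> ClusterAssignment:
    """K-means with elbow selection.

    Runs K-means for k = 1..k_max on min-max scaled genes; on the
    (k, within-cluster sum of squares) curve with both axes min-max scaled to
    [0, 1], picks the k closest to the origin.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    X = _minmax_genes(expr_selected)
    k_max = min(k_max, X.shape[0])
    inertias, fits = [], []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertias.append(km.inertia_)
        fits.append(km.labels_)
    ks = np.arange(1, k_max + 1, dtype=np.float64)
    inert = np.asarray(inertias)
    ks_s = (ks - ks.min()) / max(ks.max() - ks.min(), 1e-12)
    in_s = (inert - inert.min()) / max(inert.max() - inert.min(), 1e-12)
    best = int(np.argmin(np.hypot(ks_s, in_s)))
    return ClusterAssignment(
        labels=_contiguous(fits[best]),
        method="kmeans_elbow",
        params={"k": best + 1, "k_max": k_max, "seed": seed},
    )


def kmeans_silhouette(
    expr_selected: np.ndarray, k_max: int = 15, seed: int = 0
) -> ClusterAssignment:
    """K-means with silhouette-based selection.

    A candidate k is invalid when some cluster's *maximum* per-sample
    silhouette falls below the dataset-average silhouette — that cluster has
    no well-placed cell. Scans k upward from 2 and stops at the first
    invalid k (once a split fractures a real cluster, every larger k is
    over-partitioned too, even though the collapsing average silhouette can
    make large k look "valid" again); returns the last valid k, or a single
    cluster when k = 2 is already invalid.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    X = _minmax_genes(expr_selected)
    k_max = min(k_max, X.shape[0] - 1)
    best_labels, best_k = None, 1
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            continue
        avg = silhouette_score(X, labels)
        per_sample = silhouette_samples(X, labels)
        valid = all(
            per_sample[labels == c].max() >= avg for c in np.unique(labels)
        )
        if not valid:
            break
        best_labels, best_k = labels, k
    if best_labels is None:
        best_labels = np.zeros(X.shape[0], dtype=np.int64)
    return ClusterAssignment(
        labels=_contiguous(best_labels),
        method="kmeans_silhouette",
        params={"k": best_k, "k_max": k_max, "seed": seed},
    )


#: AP-merge edges with transition probability below this are dropped before
#: Louvain (z > ~3.1 combined SDs: effectively unreachable waypoint). Without
#: pruning, any positive weight — even ~1e-16 — joins two lone AP clusters,
#: because modularity on a single-edge graph is maximized by one community.
MERGE_MIN_PROBABILITY = 1e-3


def ap_merge_cluster(expr_selected: np.ndarray, seed: int = 0) -> ClusterAssignment:
    """Affinity propagation with SD-based cluster merging.

    AP runs on the negative squared Euclidean distance between rows of the
    cell-cell Spearman matrix, with the preference vector initialized to the
    row-wise minimum. Because AP fragments large homogeneous populations,
    fragments are merged: for each cluster pair, the number of combined
    within-cluster standard deviations needed to reach the halfway point
    between the two exemplars (in affinity space) is converted to a
    transition probability with the normal survival function; the dense
    cluster x cluster probability matrix goes through weighted Louvain and
    AP clusters sharing a community are merged.
    """
    expr_selected = np.asarray(expr_selected, dtype=np.float64)
    if expr_selected.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    S = _cell_spearman(expr_selected)
    A = -squareform(pdist(S, metric="sqeuclidean"))
    preference = A.min(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(
            affinity="precomputed", preference=preference, random_state=seed,
            max_iter=500,
        ).fit(A)
    labels = ap.labels_
    exemplars = ap.cluster_centers_indices_
    if exemplars is None or len(exemplars) == 0 or np.any(labels < 0):
        warnings.warn("affinity propagation did not converge; returning one cluster")
        return ClusterAssignment(
            labels=np.zeros(A.shape[0], dtype=np.int64),
            method="ap_merge", params={"seed": seed, "converged": False},
        )
    k = len(exemplars)
    if k == 1:
        return ClusterAssignment(
            labels=_contiguous(labels), method="ap_merge",
            params={"seed": seed, "n_ap_clusters": 1},
        )
    # within-cluster spread: SD of member distances to the exemplar, in
    # affinity space (rows of A)
    sds = np.zeros(k)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        dists = np.linalg.norm(A[members] - A[exemplars[c]], axis=1)
        sds[c] = dists.std()
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            half = 0.5 * np.linalg.norm(A[exemplars[i]] - A[exemplars[j]])
            denom = sds[i] + sds[j]
            if half == 0.0:
                z = 0.0
            elif denom == 0.0:
                z = np.inf
            else:
                z = half / denom
            p = norm.sf(z)
            if p < MERGE_MIN_PROBABILITY:
                p = 0.0
            P[i, j] = P[j, i] = p
    merged = louvain_cluster(P, seed=seed)
    final = merged.labels[labels]
    log.info("ap_merge: %d AP clusters merged into %d", k, int(final.max()) + 1)
    return ClusterAssignment(
        labels=_contiguous(final),
        method="ap_merge",
        params={"seed": seed, "n_ap_clusters": k},
    )
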