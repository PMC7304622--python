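"""Spectral relevance analysis (SpRAy) over collections of relevance maps.

The pipeline condenses each relevance map into a 56x56 descriptor
(crop tightly to the otolith contour, resize to a common intermediate
size with total-mass renormalization, then sum-pool over a regular
grid), builds a binary k-nearest-neighbour affinity graph with
``k = ceil(ln n)``, partitions it with normalized spectral clustering
into two clusters, scores the partition against age-group labels with
a best-matching F1, and embeds the samples in 2-D with t-SNE on
graph-derived pairwise distances for visual inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components, shortest_path
from skimage.measure import block_reduce
from skimage.transform import resize as _resize
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import f1_score
from sklearn.neighbors import kneighbors_graph

DESCRIPTOR_SIZE = 56
INTERMEDIATE_SIZE = 112


@dataclass
class HeatmapDescriptor:
    """Sum-downsampled relevance map used for clustering/averaging."""

    grid: np.ndarray  # (56, 56), non-negative under alpha1-beta0
    sample_id: str
    predicted_age: int
    variant: str


@dataclass
class AffinityGraph:
    matrix: np.ndarray  # (n, n) symmetric, non-negative, zero diagonal
    k: int
    n: int


@dataclass
class ClusterResult:
    labels: np.ndarray  # values in {0, 1}
    f1: float
    group_labels: np.ndarray


@dataclass
class Embedding2D:
    coordinates: np.ndarray  # (n, 2)
    seed: int


# ---------------------------------------------------------------------------
# descriptor preprocessing


def crop_to_contour(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tight bounding-box crop of the relevance map along the otolith
    contour; relevance outside the box (background noise) is discarded."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot crop with an empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return np.asarray(scores)[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def resize_preserving_mass(scores: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize rescaled so the total relevance is unchanged."""
    total = float(np.sum(scores))
    out = _resize(np.asarray(scores, dtype=float), out_shape, order=1,
                  anti_aliasing=False, preserve_range=True)
    out_total = float(np.sum(out))
    if out_total != 0.0:
        out *= total / out_total
    return out


def downsample_sum(scores: np.ndarray, out_size: int = DESCRIPTOR_SIZE) -> np.ndarray:
    """Sum pixels over a regular grid; conserves total relevance."""
    scores = np.asarray(scores, dtype=float)
    h, w = scores.shape
    if out_size > h or out_size > w:
        raise ValueError("out_size larger than the input map")
    if h % out_size or w % out_size:
        raise ValueError("input size must be a multiple of out_size")
    return block_reduce(scores, (h // out_size, w // out_size), np.sum)


def make_descriptor(
    scores: np.ndarray,
    mask: np.ndarray,
    sample_id: str = "",
    predicted_age: int = 0,
    variant: str = "baseline",
    out_size: int = DESCRIPTOR_SIZE,
    intermediate_size: int = INTERMEDIATE_SIZE,
) -> HeatmapDescriptor:
    """crop -> mass-preserving resize to the common intermediate size ->
    sum-pool to ``out_size``."""
    cropped = crop_to_contour(scores, mask)
    resized = resize_preserving_mass(cropped, (intermediate_size, intermediate_size))
    grid = downsample_sum(resized, out_size)
    return HeatmapDescriptor(grid=grid, sample_id=sample_id,
                             predicted_age=predicted_age, variant=variant)


def descriptor_matrix(descriptors: list[HeatmapDescriptor]) -> np.ndarray:
    return np.stack([d.grid.ravel() for d in descriptors])


# ---------------------------------------------------------------------------
# affinity graph and spectral clustering


def knn_k(n: int) -> int:
    """Neighbour count k = ceil(ln n) (natural log, at least 1)."""
    return max(int(np.ceil(np.log(n))), 1)


def build_affinity(X: np.ndarray | list[HeatmapDescriptor],
                   k: int | None = None) -> AffinityGraph:
    """Binary Euclidean k-NN graph, symmetrized by union, zero diagonal."""
    if isinstance(X, list):
        X = descriptor_matrix(X)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to build an affinity graph")
    if k is None:
        k = knn_k(n)
    A = kneighbors_graph(X, n_neighbors=min(k, n - 1), mode="connectivity",
                         include_self=False).toarray()
    A = np.maximum(A, A.T)  # union symmetrization
    np.fill_diagonal(A, 0.0)
    return AffinityGraph(matrix=A, k=k, n=n)


def spectral_cluster(graph: AffinityGraph, n_clusters: int = 2,
                     seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering (symmetric Laplacian, smallest
    eigenvectors, row-normalized embedding, seeded k-means)."""
    A = graph.matrix
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > n_clusters:
        warnings.warn(
            f"affinity graph has {n_comp} connected components "
            f"(> {n_clusters} clusters); clustering proceeds", stacklevel=2)
    deg = A.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(graph.n) - (d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :])
    _, vecs = eigh(L, subset_by_index=[0, n_clusters - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    U = vecs / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(U)


def clustering_f1(labels: np.ndarray, group_labels: np.ndarray) -> float:
    """Binary F1 under the cluster-to-group matching (out of the two
    possible) that maximizes it."""
    labels = np.asarray(labels)
    group_labels = np.asarray(group_labels)
    if labels.shape != group_labels.shape:
        raise ValueError("labels and group_labels must have the same length")
    uniq = np.unique(group_labels)
    if len(uniq) > 2:
        raise ValueError("clustering_f1 expects at most 2 groups")
    y = (group_labels == uniq[-1]).astype(int)
    lab = (labels == np.unique(labels)[-1]).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = [f1_score(y, lab, zero_division=0),
                  f1_score(y, 1 - lab, zero_division=0)]
    return float(max(scores))


def embed_tsne(graph: AffinityGraph, seed: int = 0,
               perplexity: float = 30.0) -> Embedding2D:
    """2-D t-SNE on pairwise distances derived from the affinity graph.

    Distances are shortest-path hop counts on the k-NN graph;
    disconnected pairs are capped at twice the largest finite distance.
    """
    if graph.n < 5:
        raise ValueError("need at least 5 samples for a t-SNE embedding")
    D = shortest_path(graph.matrix, method="D", directed=False,
                      unweighted=True)
    finite = D[np.isfinite(D)]
    cap = 2.0 * float(finite.max()) if finite.size else 1.0
    D[~np.isfinite(D)] = max(cap, 1.0)
    perplexity = min(perplexity, (graph.n - 1) / 3.0)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=seed, perplexity=perplexity)
    coords = tsne.fit_transform(D)
    return Embedding2D(coordinates=np.asarray(coords, dtype=float), seed=seed)


# ---------------------------------------------------------------------------
# estimator facade


class SpRAy(ClusterMixin, BaseEstimator):
    """Spectral relevance analysis as a scikit-learn style clusterer.

    Parameters
    ----------
    n_clusters : number of clusters (2 for a pair of age groups).
    k : neighbour count for the affinity graph; ``None`` uses ceil(ln n).
    random_state : seed for the k-means step (and t-SNE via
        :meth:`embed`).

    Attributes (after :meth:`fit`)
    ------------------------------
    affinity_ : AffinityGraph built from the descriptors.
    labels_ : cluster label (0/1) per sample.
    """

    def __init__(self, n_clusters: int = 2, k: int | None = None,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: (n, d) descriptor matrix or a list of HeatmapDescriptor."""
        if isinstance(X, list):
            X = descriptor_matrix(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D descriptor matrix")
        self.affinity_ = build_affinity(X, k=self.k)
        self.labels_ = spectral_cluster(self.affinity_,
                                        n_clusters=self.n_clusters,
                                        seed=self.random_state)
        return self

    def score_f1(self, group_labels) -> float:
        """Best-matching F1 of the fitted partition against group labels."""
        return clustering_f1(self.labels_, np.asarray(group_labels))

    def embed(self, perplexity: float = 30.0) -> Embedding2D:
        """2-D t-SNE embedding of the fitted affinity graph."""
        return embed_tsne(self.affinity_, seed=self.random_state,
                          perplexity=perplexity)


def permutation_null_f1(labels: np.ndarray, group_labels: np.ndarray,
                        n_permutations: int = 199, seed: int = 0) -> np.ndarray:
    """F1 distribution under random relabelling of the groups — the
    chance level against which an observed clustering F1 is judged."""
    rng = np.random.default_rng(seed)
    group_labels = np.asarray(group_labels)
    return np.array([
        clustering_f1(labels, rng.permutation(group_labels))
        for _ in range(n_permutations)
    ])
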