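"""Clustering of the reconstructed expression and spatial refinement.

The reconstructed matrix H is reduced to 20 principal components; domains
come either from a tied-covariance Gaussian mixture (the mclust "EEE"
analogue, used when the number of domains is known) or from Leiden
community detection on a 15-nearest-neighbor graph of the embedding
(resolution 0.5, used otherwise).  A single refinement pass then reassigns
every spot to the most frequent label within a circular neighborhood of
radius r (native coordinate units, default 50); ties keep the spot's
current label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph


@dataclass
class ClusterResult:
    """Labels before/after spatial refinement plus the embedding used."""

    embedding: np.ndarray
    labels_raw: np.ndarray
    labels_refined: np.ndarray
    method: str
    n_clusters: int

    def save_csv(self, path: str | Path, spot_ids=None) -> None:
        pd.DataFrame(
            {
                "spot_id": spot_ids if spot_ids is not None else np.arange(len(self.labels_raw)),
                "label_raw": self.labels_raw,
                "label_refined": self.labels_refined,
            }
        ).to_csv(path, index=False)


def reduce_pca(H: np.ndarray, pca_dim: int = 20) -> np.ndarray:
    """Column-centered PCA scores with a deterministic sign convention.

    Components are ordered by decreasing explained variance; each is
    oriented so its largest-magnitude loading is positive.
    """
    H = np.asarray(H, dtype=np.float64)
    if pca_dim > min(H.shape):
        raise ValueError(f"pca_dim={pca_dim} exceeds min(N, M)={min(H.shape)}")
    pca = PCA(n_components=pca_dim, svd_solver="full")
    scores = pca.fit_transform(H)
    if np.any(pca.singular_values_ <= 1e-10 * max(1.0, pca.singular_values_[0])):
        raise ValueError(f"matrix rank is below pca_dim={pca_dim}")
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(pca_dim), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return scores * flip[None, :]


def cluster_gmm(embedding: np.ndarray, n_clusters: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Tied-covariance Gaussian mixture, best initialization by likelihood.

    Shared full covariance across components mirrors the mclust "EEE"
    model conventionally used for spatial-domain assignment.  EM is started
    both from a Ward agglomerative partition — the hierarchical
    initialization mclust itself uses — and from ``n_init`` seeded k-means
    restarts; the converged fit with the highest log-likelihood wins.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > embedding.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds {embedding.shape[0]} points")
    best = GaussianMixture(
        n_components=n_clusters,
        covariance_type="tied",
        n_init=n_init,
        random_state=seed,
        max_iter=300,
    ).fit(embedding)
    tree = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(embedding)
    resp = np.zeros((embedding.shape[0], n_clusters))
    resp[np.arange(embedding.shape[0]), tree] = 1.0
    hier = GaussianMixture(
        n_components=n_clusters,
        covariance_type="tied",
        means_init=(resp.T @ embedding) / resp.sum(axis=0)[:, None],
        weights_init=resp.sum(axis=0) / embedding.shape[0],
        random_state=seed,
        max_iter=300,
    ).fit(embedding)
    if hier.score(embedding) > best.score(embedding):
        best = hier
    return best.predict(embedding)


def cluster_leiden(
    embedding: np.ndarray, resolution: float = 0.5, seed: int = 0, n_neighbors: int = 15
) -> np.ndarray:
    """Leiden communities on a KNN graph of the embedding.

    Labels are relabeled to consecutive integers by descending community
    size, so label 0 is always the largest domain.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    k = min(n_neighbors, n - 1)
    adj = kneighbors_graph(embedding, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)], kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[raw]


def refine_labels(labels: np.ndarray, coords: np.ndarray, r: float = 50.0) -> np.ndarray:
    """One majority-vote pass over circular spatial neighborhoods.

    The neighborhood of a spot is every spot (itself included) within
    Euclidean distance r.  Each spot is reassigned to the modal label of
    its neighborhood; when the mode is tied the spot keeps its current
    label.  A single pass never introduces labels absent from the input.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=np.float64)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels and coords disagree on the number of spots")
    if r <= 0:
        raise ValueError("radius must be positive")
    uniq, enc = np.unique(labels, return_inverse=True)
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r)
    out = enc.copy()
    for i, nbrs in enumerate(neighborhoods):
        counts = np.bincount(enc[nbrs], minlength=len(uniq))
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            out[i] = winners[0]
        # tie -> keep current label
    return uniq[out]
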