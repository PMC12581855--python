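"""Evaluation metrics.

Supervised agreement with reference labels (ARI, NMI), batch mixing of an
integrated embedding (iLISI), and unsupervised spatial coherence of a
domain labeling (silhouette on the embedding, PAS on spatial neighborhoods,
CHAOS on within-domain spatial compactness).

Conventions pinned here: NMI normalizes mutual information by the
arithmetic mean of the entropies; iLISI uses k = 30 embedding neighbors;
PAS uses the 10 nearest spatial neighbors; CHAOS z-scores the coordinates
before measuring 1-nearest-neighbor distances, making it scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, silhouette_score


@dataclass
class MetricReport:
    """All computed metrics; optional ones are None when not applicable."""

    ari: float | None = None
    nmi: float | None = None
    ilisi: float | None = None
    silhouette: float | None = None
    pas: float | None = None
    chaos: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair counting with expected-index correction)."""
    a, b = _check_lengths(labels_a, labels_b)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ilisi(embedding: np.ndarray, batch_labels, k: int = 30) -> float:
    """Local inverse Simpson's index of batch mixing.

    For every spot, the inverse Simpson's index 1 / sum_b p_b^2 of batch
    proportions among its k nearest embedding neighbors (self excluded),
    averaged over spots.  1 means unmixed neighborhoods; B (number of
    batches) means perfect mixing.  Distance ties are broken by ascending
    index so degenerate embeddings remain well defined.
    """
    embedding = np.atleast_2d(np.asarray(embedding, dtype=np.float64))
    if embedding.shape[0] == 1:
        embedding = embedding.T
    batch = np.asarray(batch_labels)
    n = embedding.shape[0]
    if batch.shape[0] != n:
        raise ValueError("batch_labels length must match embedding rows")
    uniq, enc = np.unique(batch, return_inverse=True)
    if len(uniq) == 1:
        return 1.0
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    for b in range(len(uniq)):
        if np.sum(enc == b) < 2:
            warnings.warn(f"batch {uniq[b]!r} has fewer than 2 members", stacklevel=2)
    d = cdist(embedding, embedding)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    props = np.stack(
        [(enc[order] == b).mean(axis=1) for b in range(len(uniq))], axis=1
    )
    simpson = (props**2).sum(axis=1)
    return float((1.0 / simpson).mean())


def pas(labels, coords, k: int = 10) -> float:
    """Fraction of spots disagreeing with their spatial neighborhood mode.

    The neighborhood is the k nearest spatial neighbors (self excluded);
    a spot counts as concordant when its own label ties for the mode.
    """
    labels, coords = _check_lengths(labels, np.asarray(coords, dtype=np.float64))
    uniq, enc = np.unique(labels, return_inverse=True)
    n = labels.shape[0]
    kk = min(k, n - 1)
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :kk]
    abnormal = 0
    for i in range(n):
        counts = np.bincount(enc[order[i]], minlength=len(uniq))
        if counts[enc[i]] < counts.max():
            abnormal += 1
    return abnormal / n


def chaos(labels, coords) -> float:
    """Mean within-cluster 1-nearest-neighbor distance on z-scored coords.

    Lower values indicate spatially compact clusters.  Singleton clusters
    have no within-cluster neighbor and are skipped with a warning.
    """
    labels, coords = _check_lengths(labels, np.asarray(coords, dtype=np.float64))
    sd = coords.std(axis=0)
    sd[sd == 0] = 1.0
    zc = (coords - coords.mean(axis=0)) / sd
    vals = []
    for lab in np.unique(labels):
        pts = zc[labels == lab]
        if pts.shape[0] < 2:
            warnings.warn(f"cluster {lab!r} is a singleton; skipped in CHAOS", stacklevel=2)
            continue
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        vals.append(dist[:, 1].mean())
    if not vals:
        raise ValueError("no cluster has at least 2 members")
    return float(np.mean(vals))


def spatial_coherence(labels, coords, embedding) -> dict[str, float]:
    """Silhouette (embedding), PAS and CHAOS (space) for one labeling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 distinct labels")
    return {
        "silhouette": float(silhouette_score(np.asarray(embedding), labels, metric="euclidean")),
        "pas": pas(labels, coords),
        "chaos": chaos(labels, coords),
    }


def metric_report(
    pred,
    truth=None,
    embedding: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    batch=None,
) -> MetricReport:
    """Assemble every metric computable from the provided inputs."""
    report = MetricReport()
    if truth is not None:
        report.ari = ari(pred, truth)
        report.nmi = nmi(pred, truth)
    if embedding is not None and batch is not None:
        report.ilisi = ilisi(embedding, batch)
    if coords is not None and embedding is not None and len(np.unique(pred)) >= 2:
        sc = spatial_coherence(pred, coords, embedding)
        report.silhouette = sc["silhouette"]
        report.pas = sc["pas"]
        report.chaos = sc["chaos"]
    return report
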