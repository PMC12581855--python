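"""Spatial neighborhood graphs.

Each tissue slice becomes an undirected graph over its spots: every spot is
linked to its K nearest neighbors in Euclidean coordinate space and the
directed relation is symmetrized by union.  For graph convolution the
adjacency is normalized as D^{-1/2} (A + I) D^{-1/2}, where D is the degree
matrix of A + I — adding the self-loop before computing degrees keeps the
normalization defined even for isolated nodes.  Multislice experiments
stack per-slice adjacencies into one block-diagonal matrix, which preserves
within-slice neighborhoods and introduces no cross-slice edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

# above this size an exact N x N distance matrix stops being reasonable
_BRUTE_FORCE_LIMIT = 8192


@dataclass
class SpatialGraph:
    """Binary symmetric KNN adjacency and its convolution normalization."""

    A: np.ndarray  # (N, N) binary, symmetric, zero diagonal
    A_norm: np.ndarray  # D^{-1/2} (A + I) D^{-1/2}
    degrees: np.ndarray  # row sums of A

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.A, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def save_edge_list(self, path: str | Path, spot_ids: Sequence[str] | None = None) -> None:
        """Write the undirected edges as a two-column TSV for inspection."""
        with open(path, "w") as fh:
            for a, b in self.edge_list():
                if spot_ids is not None:
                    fh.write(f"{spot_ids[a]}\t{spot_ids[b]}\n")
                else:
                    fh.write(f"{a}\t{b}\n")


@dataclass
class MultisliceGraph:
    """Block-diagonal adjacency over the concatenated spots of all slices."""

    A_block: np.ndarray
    A_norm: np.ndarray
    slice_sizes: list[int]
    slice_of_spot: np.ndarray

    @property
    def n_spots(self) -> int:
        return self.A_block.shape[0]


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors per spot, self excluded.

    Distance ties are broken by ascending spot index (stable sort on the
    full distance matrix), so graph construction is deterministic even for
    duplicated coordinates.  Large inputs fall back to a KD-tree.
    """
    n = coords.shape[0]
    if n <= _BRUTE_FORCE_LIMIT:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")
        return order[:, :k]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    out = np.empty((n, k), dtype=int)
    for i in range(n):  # drop self wherever it lands in the result row
        row = idx[i][idx[i] != i][:k]
        out[i] = row
    return out


def build_knn_graph(coords: np.ndarray, k: int) -> SpatialGraph:
    """Symmetrized K-nearest-neighbor graph of the spot coordinates."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) matrix")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    nbr = _knn_indices(coords, k)
    A = np.zeros((n, n))
    A[np.repeat(np.arange(n), k), nbr.ravel()] = 1.0
    A = np.maximum(A, A.T)  # union symmetrization: undirected graph
    degrees = A.sum(axis=1).astype(int)
    return SpatialGraph(A=A, A_norm=normalize_adjacency(A), degrees=degrees)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric convolution normalization D^{-1/2} (A + I) D^{-1/2}.

    D is the degree matrix of A + I; the largest eigenvalue of the result
    is exactly 1 and the spectrum lies in [-1, 1].
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def identity_graph(n: int) -> SpatialGraph:
    """A graph with no spatial edges (A = 0, normalized adjacency = I).

    The spatial-ablation baseline: graph convolution degenerates to a plain
    linear layer and the contrastive loss sees no neighborhood positives.
    """
    return SpatialGraph(A=np.zeros((n, n)), A_norm=np.eye(n), degrees=np.zeros(n, dtype=int))


def assemble_multislice(graphs: Sequence[SpatialGraph]) -> MultisliceGraph:
    """Stack per-slice adjacencies into one block-diagonal graph.

    Normalization commutes with the block structure, so ``A_norm`` is the
    block-diagonal stack of the per-slice normalized adjacencies.
    """
    if len(graphs) == 0:
        raise ValueError("need at least one graph")
    sizes = [g.n_spots for g in graphs]
    T = sum(sizes)
    A_block = np.zeros((T, T))
    offset = 0
    for g in graphs:
        s = slice(offset, offset + g.n_spots)
        A_block[s, s] = g.A
        offset += g.n_spots
    slice_of_spot = np.concatenate([np.full(s, i, dtype=int) for i, s in enumerate(sizes)])
    return MultisliceGraph(
        A_block=A_block,
        A_norm=normalize_adjacency(A_block),
        slice_sizes=sizes,
        slice_of_spot=slice_of_spot,
    )
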