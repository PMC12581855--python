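"""End-to-end pipelines: preprocess -> graph -> train -> cluster -> refine."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterResult, cluster_gmm, cluster_leiden, reduce_pca, refine_labels
from .config import RunConfig
from .datasets import ExpressionDataset, concatenate_datasets
from .graphs import MultisliceGraph, SpatialGraph, assemble_multislice, build_knn_graph
from .preprocess import normalize_expression, prepare_multislice, select_hvgs
from .train import TrainResult, train_multislice, train_on_matrix


@dataclass
class PipelineResult:
    """Everything a run produces: input view, model output, and labels."""

    dataset: ExpressionDataset  # single slice, or the concatenated slices
    X: np.ndarray  # the model input (z-scored log expression)
    graph: SpatialGraph | MultisliceGraph
    training: TrainResult
    clustering: ClusterResult


def _cluster_and_refine(
    H: np.ndarray,
    coords: np.ndarray,
    config: RunConfig,
    n_clusters: int | None,
    slice_of_spot: np.ndarray | None = None,
) -> ClusterResult:
    # H's centered rank is bounded by the embedding dimension, so
    # small-embedding runs reduce to fewer than pca_dim components
    rank_cap = int(np.linalg.matrix_rank(H - H.mean(axis=0)))
    embedding = reduce_pca(H, min(config.pca_dim, rank_cap))
    if n_clusters is not None:
        labels = cluster_gmm(embedding, n_clusters, seed=config.seed, n_init=config.gmm_n_init)
        method = "gmm"
    else:
        labels = cluster_leiden(
            embedding, resolution=config.leiden_resolution, seed=config.seed,
            n_neighbors=config.leiden_knn,
        )
        method = "leiden"
    if slice_of_spot is None:
        refined = refine_labels(labels, coords, r=config.refine_radius)
    else:
        # slices occupy overlapping coordinate frames: refine within each slice
        refined = labels.copy()
        for s in np.unique(slice_of_spot):
            mask = slice_of_spot == s
            refined[mask] = refine_labels(labels[mask], coords[mask], r=config.refine_radius)
    return ClusterResult(
        embedding=embedding,
        labels_raw=np.asarray(labels),
        labels_refined=np.asarray(refined),
        method=method,
        n_clusters=int(np.unique(labels).size),
    )


def run_single_slice(
    dataset: ExpressionDataset,
    config: RunConfig | None = None,
    n_clusters: int | None = None,
    graph: SpatialGraph | None = None,
) -> PipelineResult:
    """Full single-slice pipeline.

    ``n_clusters`` selects the tied-covariance GMM; when omitted it is
    taken from the ground-truth labels if present, otherwise Leiden at the
    configured resolution decides the number of domains.  Passing ``graph``
    overrides KNN construction (e.g. for ablation baselines).
    """
    config = config or RunConfig()
    if n_clusters is None and dataset.labels is not None:
        n_clusters = int(np.unique(np.asarray(dataset.labels)).size)
    if dataset.normalized:
        X = np.asarray(dataset.counts, dtype=np.float64)
    else:
        idx = select_hvgs(dataset, config.n_hvg)
        X = normalize_expression(dataset, idx).X
    if graph is None:
        graph = build_knn_graph(dataset.coords, config.n_neighbors)
    training = train_on_matrix(X, graph.A, graph.A_norm, config)
    clustering = _cluster_and_refine(training.H_final, dataset.coords, config, n_clusters)
    return PipelineResult(dataset=dataset, X=X, graph=graph, training=training, clustering=clustering)


def run_multislice(
    slices: list[ExpressionDataset],
    config: RunConfig | None = None,
    n_clusters: int | None = None,
) -> PipelineResult:
    """Joint pipeline over multiple slices via the block-diagonal graph."""
    config = config or RunConfig()
    if len(slices) < 2:
        raise ValueError("run_multislice needs at least 2 slices")
    X, shared, _sizes = prepare_multislice(slices, config.n_hvg_per_slice)
    graphs = [build_knn_graph(s.coords, config.n_neighbors) for s in slices]
    mgraph = assemble_multislice(graphs)
    training = train_multislice(X, mgraph, config)

    concat = concatenate_datasets(
        [_subset_genes(s, shared) for s in slices]
    )
    if n_clusters is None and concat.labels is not None:
        n_clusters = int(np.unique(np.asarray(concat.labels)).size)
    clustering = _cluster_and_refine(
        training.H_final, concat.coords, config, n_clusters, slice_of_spot=mgraph.slice_of_spot
    )
    return PipelineResult(dataset=concat, X=X, graph=mgraph, training=training, clustering=clustering)


def _subset_genes(s: ExpressionDataset, genes: list[str]) -> ExpressionDataset:
    pos = {g: i for i, g in enumerate(s.gene_names)}
    idx = [pos[g] for g in genes]
    return ExpressionDataset(
        counts=np.asarray(s.counts)[:, idx],
        coords=s.coords,
        gene_names=list(genes),
        spot_ids=s.spot_ids,
        labels=s.labels,
        slice_id=s.slice_id,
        normalized=s.normalized,
    )
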