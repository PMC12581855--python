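"""Expression preprocessing: HVG selection, normalization, standardization.

The pipeline applied to each slice is: subset to highly variable genes,
library-size normalize every spot to the median total count, log(1 + x),
then z-score each gene (population denominator ``N``).  Constant genes map
to all-zero columns rather than raising.  Low-plex platforms are handled by
the HVG rule itself: when the panel has no more genes than requested, all
genes are retained.

The HVG statistic is the Seurat-style normalized dispersion: per-gene
dispersion (variance over mean of library-size-normalized counts), z-scored
within bins of genes of similar mean so that highly expressed genes do not
dominate the ranking.  Ties are broken by ascending gene index, which makes
the selection deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import ExpressionDataset

# genes are binned by mean expression before z-scoring dispersions; the 20
# bins conventional for genome-wide panels assume thousands of genes, so the
# bin count adapts to keep roughly _GENES_PER_BIN genes per bin — a z-score
# within a bin of two or three genes would be quantized noise
_MAX_BINS = 20
_GENES_PER_BIN = 20


@dataclass
class NormalizedExpression:
    """Z-scored log expression on the selected genes: the model input X."""

    X: np.ndarray  # (n_spots, n_selected), zero mean / unit variance per gene
    selected_genes: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape[1] != len(self.selected_genes):
            raise ValueError("X columns must match selected_genes")


def _library_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale each spot to the median total count; error on empty spots."""
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"spot {zero[0]} has zero total count; remove empty spots first")
    return counts * (np.median(totals) / totals)[:, None]


def normalized_dispersion(counts: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (var/mean), z-scored within mean-expression bins."""
    norm = _library_normalize(np.asarray(counts, dtype=np.float64))
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    G = counts.shape[1]
    n_bins = max(1, min(_MAX_BINS, G // _GENES_PER_BIN))
    if n_bins == 1:
        bins = np.zeros(G, dtype=int)
    else:
        quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(quantiles, mean, side="right")
    z = np.zeros(G)
    for b in np.unique(bins):
        mask = bins == b
        mu, sd = disp[mask].mean(), disp[mask].std()  # population sd
        z[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0
    return z


def select_hvgs(dataset: ExpressionDataset, n_top: int) -> np.ndarray:
    """Indices (ascending) of the ``n_top`` most variable genes.

    If the dataset has at most ``n_top`` genes — targeted low-plex panels —
    every gene is retained.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    counts = np.asarray(dataset.counts, dtype=np.float64)
    if not np.any(counts):
        raise ValueError("expression matrix is all zero; nothing to select")
    G = counts.shape[1]
    if G <= n_top:
        return np.arange(G)
    z = normalized_dispersion(counts)
    # sort by descending dispersion, ties by ascending gene index
    order = np.lexsort((np.arange(G), -z))
    return np.sort(order[:n_top])


def normalize_expression(dataset: ExpressionDataset, gene_idx: Sequence[int]) -> NormalizedExpression:
    """Library-size normalize -> subset to ``gene_idx`` -> log1p -> z-score.

    Library sizes are the spots' total counts over the *full* gene panel
    (the toolkit convention); the HVG subset is applied afterwards.
    """
    gene_idx = np.asarray(gene_idx, dtype=int)
    if gene_idx.size == 0:
        raise ValueError("gene_idx is empty")
    if gene_idx.min() < 0 or gene_idx.max() >= dataset.n_genes:
        raise ValueError("gene_idx out of range")
    counts = np.asarray(dataset.counts, dtype=np.float64)
    logged = np.log1p(_library_normalize(counts)[:, gene_idx])
    X = _zscore_columns(logged)
    return NormalizedExpression(X=X, selected_genes=[dataset.gene_names[i] for i in gene_idx])


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population denominator N
    out = X - mean
    # constant up to float rounding counts as constant: amplifying an sd of
    # ~1e-16 to unit variance would turn pure noise into signal
    nonconst = sd > 1e-10 * np.maximum(1.0, np.abs(mean))
    out[:, nonconst] /= sd[nonconst]
    out[:, ~nonconst] = 0.0  # constant genes -> all-zero columns
    return out


def shared_hvg_intersection(
    slices: Sequence[ExpressionDataset], n_top_per_slice: int = 5000
) -> list[str]:
    """Shared HVG set across slices, ordered by the first slice's genes.

    Each slice contributes its top ``n_top_per_slice`` HVGs; the result is
    the intersection of those sets.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices for a shared HVG set")
    hvg_sets = []
    for s in slices:
        idx = select_hvgs(s, n_top_per_slice)
        hvg_sets.append({s.gene_names[i] for i in idx})
    shared = set.intersection(*hvg_sets)
    if not shared:
        raise ValueError(
            "HVG sets have an empty intersection across slices; increase n_top_per_slice"
        )
    return [g for g in slices[0].gene_names if g in shared]


def prepare_multislice(
    slices: Sequence[ExpressionDataset],
    n_top_per_slice: int = 5000,
    per_slice_scale: bool = True,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Build the concatenated model input for multislice integration.

    Each slice runs the full single-slice recipe independently —
    library-size normalization, subsetting to the shared HVGs, log(1+x),
    per-gene z-scoring — and the standardized slices are row-concatenated.
    Per-slice standardization removes per-gene multiplicative slice offsets
    (the dominant technical batch signature) before the slices ever meet,
    which is what lets the shared encoder integrate them; with
    ``per_slice_scale=False`` z-scoring instead happens once on the
    concatenated matrix, leaving the batch signal in (the uncorrected
    baseline).

    Returns ``(X, shared_genes, slice_sizes)`` with ``X`` of shape
    (total spots, shared genes).
    """
    shared = shared_hvg_intersection(slices, n_top_per_slice)
    blocks = []
    for s in slices:
        pos = {g: i for i, g in enumerate(s.gene_names)}
        idx = np.array([pos[g] for g in shared], dtype=int)
        counts = np.asarray(s.counts, dtype=np.float64)
        logged = np.log1p(_library_normalize(counts)[:, idx])
        blocks.append(_zscore_columns(logged) if per_slice_scale else logged)
    X = np.vstack(blocks)
    if not per_slice_scale:
        X = _zscore_columns(X)
    return X, shared, [s.n_spots for s in slices]
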