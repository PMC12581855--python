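"""Synthetic spatial transcriptomics data with ground-truth domains.

Spots sit on a jittered square grid partitioned into contiguous spatial
domains — horizontal stripes by default, echoing layered cortical tissue,
or Voronoi blobs.  Each domain owns a disjoint block of marker genes whose
negative-binomial mean is elevated by ``exp(log_fold_change)`` inside the
domain; all other genes share a flat baseline.  Multislice datasets share
the layout and marker structure but differ by seeded grid jitter and, when
``batch_sigma > 0``, by per-slice per-gene multiplicative factors
``exp(Normal(0, batch_sigma))`` — a purely technical batch effect that
leaves the ground-truth labels untouched.

Counts are negative binomial with gene-level means: mean mu and shape
``nb_dispersion`` give variance mu + mu^2 / nb_dispersion, matching the
overdispersion of real ST counts.  Defaults: a 25 x 25 grid (625 spots),
7 stripes, 200 genes with 10 markers per domain, base mean 1.0, shape 2.0,
grid spacing 20 coordinate units with +-2 uniform jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset


@dataclass
class SimConfig:
    """Generator settings; defaults define the reference study conditions."""

    n_spots_side: int = 25
    n_domains: int = 7
    layout: str = "stripes"
    n_genes: int = 200
    n_markers_per_domain: int = 10
    log_fold_change: float = 1.0
    nb_dispersion: float = 2.0
    base_mean: float = 1.0
    n_slices: int = 1
    batch_sigma: float = 0.0
    seed: int = 0
    grid_spacing: float = 20.0
    jitter: float = 2.0  # half-width of uniform positional jitter

    def __post_init__(self) -> None:
        if self.layout not in ("stripes", "blobs"):
            raise ValueError("layout must be 'stripes' or 'blobs'")
        if self.n_markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        for name in (
            "n_spots_side",
            "n_domains",
            "n_genes",
            "n_markers_per_domain",
            "nb_dispersion",
            "base_mean",
            "n_slices",
            "grid_spacing",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.log_fold_change < 0 or self.batch_sigma < 0 or self.jitter < 0:
            raise ValueError("log_fold_change, batch_sigma and jitter must be nonnegative")
        if self.n_domains > self.n_spots_side and self.layout == "stripes":
            raise ValueError("stripes need n_domains <= n_spots_side")


def _domain_labels(config: SimConfig, grid_rc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    side = config.n_spots_side
    if config.layout == "stripes":
        # contiguous horizontal bands of (nearly) equal height
        return grid_rc[:, 0] * config.n_domains // side
    centers = rng.uniform(0, side, size=(config.n_domains, 2))
    d = ((grid_rc[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def _marker_matrix(config: SimConfig) -> np.ndarray:
    """(n_domains, n_genes) indicator of which gene marks which domain."""
    markers = np.zeros((config.n_domains, config.n_genes))
    m = config.n_markers_per_domain
    for k in range(config.n_domains):
        markers[k, k * m : (k + 1) * m] = 1.0
    return markers


def simulate_slice(config: SimConfig, slice_index: int = 0) -> ExpressionDataset:
    """One slice with ground-truth domain labels.

    The domain layout and marker assignment depend only on ``config.seed``;
    jitter, batch factors and count noise additionally depend on
    ``slice_index``, so slices of one configuration are replicates of the
    same tissue.
    """
    layout_rng = np.random.default_rng([config.seed, 0])
    rng = np.random.default_rng([config.seed, slice_index + 1])
    side = config.n_spots_side
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    grid_rc = np.column_stack([rr.ravel(), cc.ravel()])
    labels = _domain_labels(config, grid_rc, layout_rng)

    coords = grid_rc[:, ::-1] * config.grid_spacing  # (x, y) = (col, row)
    coords = coords + rng.uniform(-config.jitter, config.jitter, size=coords.shape)

    markers = _marker_matrix(config)
    mu = config.base_mean * np.exp(config.log_fold_change * markers[labels])
    if config.batch_sigma > 0:
        batch_factor = np.exp(rng.normal(0.0, config.batch_sigma, size=config.n_genes))
        mu = mu * batch_factor[None, :]

    # negative binomial via its shape/prob parametrization
    shape = config.nb_dispersion
    p = shape / (shape + mu)
    counts = rng.negative_binomial(shape, p).astype(np.float64)

    n = side * side
    return ExpressionDataset(
        counts=counts,
        coords=coords,
        gene_names=[f"gene_{g}" for g in range(config.n_genes)],
        spot_ids=[f"spot_{i}" for i in range(n)],
        labels=labels.astype(int),
    )


def simulate_multislice(config: SimConfig) -> list[ExpressionDataset]:
    """Slices sharing layout and markers, differing by jitter and batch."""
    if config.n_slices < 2:
        raise ValueError("simulate_multislice needs n_slices >= 2")
    return [simulate_slice(config, slice_index=i) for i in range(config.n_slices)]
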