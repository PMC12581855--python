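"""Run configuration: every tunable of the pipeline in one record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any


@dataclass
class RunConfig:
    """Hyperparameters of the full spatial-domain identification pipeline.

    Defaults follow the reference setting of the method: 4000 highly
    variable genes, a 6-nearest-neighbor spatial graph, a 64-dimensional
    single-layer GCN embedding trained for 500 full-batch epochs with Adam
    at learning rate 1e-3, loss weights (alpha, beta, gamma) = (10, 0.5, 0.5)
    on reconstruction / local contrastive / global contrastive terms, and
    reconstruction sub-weights (alpha1, alpha2) = (1.0, 0.5) on the feature
    and adjacency parts.  The contrastive temperature tau defaults to 0.5.

    Clustering reduces the reconstructed matrix to ``pca_dim`` = 20
    components; refinement uses a circular neighborhood of radius
    ``refine_radius`` in the dataset's native coordinate units.
    """

    n_hvg: int = 4000
    n_neighbors: int = 6
    embed_dim: int = 64
    epochs: int = 500
    learning_rate: float = 1e-3
    alpha: float = 10.0
    beta: float = 0.5
    gamma: float = 0.5
    alpha1: float = 1.0
    alpha2: float = 0.5
    temperature: float = 0.5
    pca_dim: int = 20
    refine_radius: float = 50.0
    leiden_resolution: float = 0.5
    seed: int = 0
    # secondary knobs (documented design choices, not headline parameters)
    n_hvg_per_slice: int = 5000  # per-slice HVG pool for the multislice intersection
    decoder_activation: str = "identity"  # feature decoder output activation
    global_on_projection: bool = True  # global loss on projections (else raw embeddings)
    leiden_knn: int = 15  # backbone graph for Leiden on the embedding
    gmm_n_init: int = 10  # seeded restarts for the tied-covariance GMM

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError(f"RunConfig.epochs must be nonnegative, got {self.epochs!r}")
        for f in dataclasses.fields(self):
            if f.name in ("seed", "epochs", "decoder_activation", "global_on_projection"):
                continue
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"RunConfig.{f.name} must be strictly positive, got {v!r}")
        if self.decoder_activation not in ("identity", "relu"):
            raise ValueError("decoder_activation must be 'identity' or 'relu'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
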