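"""The graph convolutional autoencoder.

A single-layer GCN encoder maps the normalized expression matrix X (N x M)
to embeddings Z = ReLU(A_norm X W_e + b_e) with embedding dimension d; a
mirrored single-layer GCN decoder reconstructs expression
H = A_norm Z W_d + b_d, and an inner-product decoder reconstructs the
adjacency as sigmoid(Z Z^T).  A two-layer MLP projection head smooths Z for
the contrastive objectives.  The second (corrupted) view shares all
parameters and the graph topology; only the feature rows are permuted.

The feature decoder's output activation defaults to the identity: the input
X is z-scored and therefore signed, which a ReLU output could never
reconstruct.  A ReLU variant remains available via ``activation="relu"``.

All forward functions accept either numpy arrays or autodiff Tensors for
the parameters, so the same code serves inference and training.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import numpy as np

from ._autodiff import Tensor, asdata, matmul, relu, sigmoid


@dataclass
class ModelParams:
    """Trainable parameters: encoder/decoder pairs and the projection head."""

    W_e: Any  # (M, d)
    B_e: Any  # (d,)
    W_d: Any  # (d, M)
    B_d: Any  # (M,)
    proj_W1: Any  # (d, d)
    proj_b1: Any  # (d,)
    proj_W2: Any  # (d, d)
    proj_b2: Any  # (d,)

    def items(self) -> list[tuple[str, Any]]:
        return [(f.name, getattr(self, f.name)) for f in fields(self)]

    def as_numpy(self) -> "ModelParams":
        return ModelParams(**{name: np.asarray(asdata(v)) for name, v in self.items()})

    def as_tensors(self) -> "ModelParams":
        return ModelParams(**{name: Tensor(asdata(v), requires_grad=True) for name, v in self.items()})


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(n_genes: int, embed_dim: int, rng: np.random.Generator) -> ModelParams:
    """Glorot-uniform weights, zero biases."""
    d = embed_dim
    return ModelParams(
        W_e=_glorot(rng, n_genes, d),
        B_e=np.zeros(d),
        W_d=_glorot(rng, d, n_genes),
        B_d=np.zeros(n_genes),
        proj_W1=_glorot(rng, d, d),
        proj_b1=np.zeros(d),
        proj_W2=_glorot(rng, d, d),
        proj_b2=np.zeros(d),
    )


def _check_2d(name: str, x: Any) -> None:
    if asdata(x).ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")


def encode(X: Any, A_norm: np.ndarray, params: ModelParams) -> Any:
    """Z = ReLU(A_norm X W_e + b_e); nonnegative embeddings (N x d)."""
    _check_2d("X", X)
    n, m = asdata(X).shape
    if A_norm.shape != (n, n):
        raise ValueError(f"A_norm shape {A_norm.shape} does not match {n} spots")
    if asdata(params.W_e).shape[0] != m:
        raise ValueError(
            f"W_e expects {asdata(params.W_e).shape[0]} genes but X has {m}"
        )
    # associate as A (X W): d << M makes this the cheap order
    return relu(matmul(A_norm, matmul(X, params.W_e)) + params.B_e)


def decode_features(
    Z: Any, A_norm: np.ndarray, params: ModelParams, activation: str = "identity"
) -> Any:
    """H = act(A_norm Z W_d + b_d), the reconstructed expression (N x M)."""
    _check_2d("Z", Z)
    n, d = asdata(Z).shape
    if A_norm.shape != (n, n):
        raise ValueError(f"A_norm shape {A_norm.shape} does not match {n} spots")
    if asdata(params.W_d).shape[0] != d:
        raise ValueError(f"W_d expects embeddings of dim {asdata(params.W_d).shape[0]}, got {d}")
    out = matmul(matmul(A_norm, Z), params.W_d) + params.B_d
    if activation == "identity":
        return out
    if activation == "relu":
        return relu(out)
    raise ValueError(f"unknown decoder activation {activation!r}")


def decode_adjacency(Z: Any) -> Any:
    """A_rec = sigmoid(Z Z^T): symmetric edge probabilities in (0, 1)."""
    _check_2d("Z", Z)
    if not np.all(np.isfinite(asdata(Z))):
        raise ValueError("Z contains non-finite entries")
    return sigmoid(Z @ Z.T)


def project(Z: Any, params: ModelParams) -> Any:
    """Two-layer MLP head: P = ReLU(Z W1 + b1) W2 + b2 (N x d)."""
    _check_2d("Z", Z)
    d = asdata(Z).shape[1]
    if asdata(params.proj_W1).shape[0] != d:
        raise ValueError(f"projection head expects dim {asdata(params.proj_W1).shape[0]}, got {d}")
    return relu(Z @ params.proj_W1 + params.proj_b1) @ params.proj_W2 + params.proj_b2


def corrupt_features(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """The corrupted view: feature rows under a uniformly random permutation.

    The graph topology is untouched; only which spot carries which
    expression vector is randomized.
    """
    X = np.asarray(X)
    return X[rng.permutation(X.shape[0])]


# ----------------------------------------------------------- checkpointing


def save_checkpoint(params: ModelParams, path: str | Path, config_json: str | None = None) -> None:
    """Flat array archive of all parameter blocks (+ optional JSON config)."""
    arrays = {name: np.asarray(asdata(v)) for name, v in params.items()}
    np.savez(Path(path), **arrays)
    if config_json is not None:
        Path(path).with_suffix(".json").write_text(config_json)


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(Path(path)) as npz:
        return ModelParams(**{k: npz[k] for k in npz.files})
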