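"""Full-batch training of the autoencoder with Adam.

Each epoch draws a fresh feature-row permutation (the corrupted view),
encodes and projects both views through the shared parameters, computes the
reconstruction term on the original view only, the neighborhood InfoNCE on
the projections, and the readout-decorrelation term, then takes one Adam
step on the weighted total.  Graphs at the scale this method targets fit in
memory, so there is no minibatching; the epoch count is fixed (no early
stopping, no schedule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse

from ._autodiff import Tensor
from .config import RunConfig
from .graphs import MultisliceGraph, SpatialGraph
from .losses import (
    LossBreakdown,
    cross_view_similarity,
    global_contrastive_loss,
    local_contrastive_loss,
    readout,
    reconstruction_loss,
    total_loss,
)
from .model import (
    ModelParams,
    corrupt_features,
    decode_adjacency,
    decode_features,
    encode,
    init_params,
    project,
)
from .preprocess import NormalizedExpression


@dataclass
class TrainResult:
    """Final parameters, embeddings/reconstruction, and the loss trajectory."""

    params: ModelParams
    Z_final: np.ndarray
    H_final: np.ndarray
    loss_history: list[LossBreakdown]


class _Adam:
    """Adam with bias correction; defaults beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            p.grad = None


def _readout_adjacency(A: np.ndarray) -> np.ndarray:
    """Raw adjacency for the readout; isolated nodes fall back to self-loops.

    KNN graphs always have degree >= 1; the fallback only fires for the
    spatial-ablation baseline (no edges), where the readout degenerates to
    a per-node identity aggregation.
    """
    if np.any(A.sum(axis=1) == 0):
        return A + np.eye(A.shape[0])
    return A


def train_on_matrix(
    X: np.ndarray,
    A: np.ndarray,
    A_norm: np.ndarray,
    config: RunConfig,
    init: ModelParams | None = None,
) -> TrainResult:
    """Core loop shared by single- and multislice training."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if A.shape != (n, n) or A_norm.shape != (n, n):
        raise ValueError("adjacency shape does not match the expression matrix")
    rng = np.random.default_rng(config.seed)
    params_np = init if init is not None else init_params(X.shape[1], config.embed_dim, rng)
    params = params_np.as_tensors()
    A_loss = A * (1.0 - np.eye(n))  # binary adjacency without self-loops
    # KNN adjacencies are ~k-sparse per row: sparse matmuls make the graph
    # convolutions and readout O(nnz * d) instead of O(N^2 * d)
    A_norm_sp = sparse.csr_matrix(A_norm)
    A_read_sp = sparse.csr_matrix(_readout_adjacency(A_loss))
    opt = _Adam([v for _, v in params.items()], lr=config.learning_rate)

    history: list[LossBreakdown] = []
    for epoch in range(config.epochs):
        X_hat = corrupt_features(X, rng)
        Z = encode(X, A_norm_sp, params)
        Z_hat = encode(X_hat, A_norm_sp, params)
        H = decode_features(Z, A_norm_sp, params, activation=config.decoder_activation)
        A_rec = decode_adjacency(Z)
        P = project(Z, params)
        P_hat = project(Z_hat, params)

        l_rec = reconstruction_loss(H, X, A_rec, A_loss, config.alpha1, config.alpha2)
        l_loc = local_contrastive_loss(P, P_hat, A_loss, config.temperature)
        if config.global_on_projection:
            R1, R2 = readout(P, A_read_sp), readout(P_hat, A_read_sp)
        else:
            R1, R2 = readout(Z, A_read_sp), readout(Z_hat, A_read_sp)
        l_glo = global_contrastive_loss(cross_view_similarity(R1, R2))

        total = config.alpha * l_rec + config.beta * l_loc + config.gamma * l_glo
        breakdown = total_loss(
            l_rec.item(), l_loc.item(), l_glo.item(), config.alpha, config.beta, config.gamma
        )
        for name, value in (
            ("reconstruction", breakdown.l_rec),
            ("local contrastive", breakdown.l_loc),
            ("global contrastive", breakdown.l_glo),
        ):
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"{name} loss became non-finite at epoch {epoch}; aborting"
                )
        total.backward()
        opt.step()
        history.append(breakdown)

    final = params.as_numpy()
    Z_final = encode(X, A_norm_sp, final)
    H_final = decode_features(Z_final, A_norm_sp, final, activation=config.decoder_activation)
    return TrainResult(params=final, Z_final=Z_final, H_final=H_final, loss_history=history)


def train(X: NormalizedExpression | np.ndarray, graph: SpatialGraph, config: RunConfig) -> TrainResult:
    """Train on a single slice."""
    Xm = X.X if isinstance(X, NormalizedExpression) else np.asarray(X)
    if Xm.shape[0] != graph.n_spots:
        raise ValueError(
            f"expression has {Xm.shape[0]} spots but the graph has {graph.n_spots}"
        )
    return train_on_matrix(Xm, graph.A, graph.A_norm, config)


def train_multislice(X_concat: np.ndarray, mgraph: MultisliceGraph, config: RunConfig) -> TrainResult:
    """Train on the concatenated slices over the block-diagonal graph.

    The loop is identical to the single-slice one; no explicit alignment
    step exists — batch mixing comes from the shared encoder and the
    contrastive objectives.
    """
    X_concat = np.asarray(X_concat)
    if X_concat.shape[0] != mgraph.n_spots:
        raise ValueError(
            f"expression has {X_concat.shape[0]} spots but the graph has {mgraph.n_spots}"
        )
    return train_on_matrix(X_concat, mgraph.A_block, mgraph.A_norm, config)


def save_training_log(history: list[LossBreakdown], path) -> None:
    """Per-epoch loss breakdown as TSV (epoch, l_rec, l_loc, l_glo, total)."""
    with open(path, "w") as fh:
        fh.write("epoch\tl_rec\tl_loc\tl_glo\ttotal\n")
        for i, b in enumerate(history):
            fh.write(f"{i}\t{b.l_rec:.10g}\t{b.l_loc:.10g}\t{b.l_glo:.10g}\t{b.total:.10g}\n")
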