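"""Training objectives.

Four terms drive the autoencoder:

* **Reconstruction** — per-spot squared error of the decoded expression
  against the input plus squared error of the inner-product adjacency
  against the binary KNN adjacency, weighted alpha1/alpha2 and averaged
  over spots.
* **Local contrastive** — a neighborhood-aware InfoNCE.  For anchor u_i in
  the original view the positives are its cross-view twin v_i, its spatial
  neighbors u_j in the same view, and the neighbors' twins v_j; every other
  node in either view is a negative.  Similarities are cosine, sharpened by
  a temperature tau, the positive terms are averaged (divided by the
  positive count) inside the logarithm, and the loss is symmetrized over
  both views.  With no edges the expression reduces exactly to the
  classical two-view InfoNCE.
* **Global contrastive** — each view is aggregated by a degree-normalized
  neighborhood readout, the d x d cosine similarity matrix between the two
  readouts' feature dimensions is computed, and its mean squared deviation
  from the identity is penalized: corresponding dimensions are pulled
  together while distinct dimensions are decorrelated.
* **Total** — alpha * rec + beta * local + gamma * global.

All operations accept numpy arrays or autodiff Tensors.  Cosine of a
zero-norm vector is defined as 0 (neutral) rather than NaN; exponentials
use per-anchor max subtraction so small temperatures stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np

from ._autodiff import asdata, exp, is_tensor, log, matmul, sigmoid, sqrt, tsum

logger = logging.getLogger(__name__)


@dataclass
class LossBreakdown:
    """Per-epoch loss components and their weighted total."""

    l_rec: float
    l_loc: float
    l_glo: float
    total: float


@dataclass
class SimilarityMatrix:
    """A d x d cross-view cosine similarity matrix; entries in [-1, 1]."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be square")
        if np.abs(self.S).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("cosine similarities must lie in [-1, 1]")


def _maybe_float(x: Any) -> Any:
    return x if is_tensor(x) else float(x)


def _row_l2_normalize(M: Any) -> Any:
    """Rows scaled to unit norm; zero rows pass through unchanged."""
    sumsq = tsum(M * M, axis=1, keepdims=True)
    zero = asdata(sumsq) == 0.0
    if np.any(zero):
        logger.warning("zero-norm rows encountered; their cosines are defined as 0")
    return M / sqrt(sumsq + zero.astype(np.float64))


def _col_l2_normalize(M: Any) -> Any:
    sumsq = tsum(M * M, axis=0, keepdims=True)
    zero = asdata(sumsq) == 0.0
    return M / sqrt(sumsq + zero.astype(np.float64))


# ------------------------------------------------------------ reconstruction


def reconstruction_loss(
    H: Any, X: Any, A_rec: Any, A: Any, alpha1: float = 1.0, alpha2: float = 0.5
) -> Any:
    """(1/N) sum_i (alpha1 ||H_i - X_i||^2 + alpha2 ||A_rec_i - A_i||^2).

    ``A`` is the binary KNN adjacency without self-loops.
    """
    if asdata(H).shape != asdata(X).shape:
        raise ValueError(f"H shape {asdata(H).shape} != X shape {asdata(X).shape}")
    if asdata(A_rec).shape != asdata(A).shape:
        raise ValueError(f"A_rec shape {asdata(A_rec).shape} != A shape {asdata(A).shape}")
    n = asdata(X).shape[0]
    if asdata(A).shape[0] != n:
        raise ValueError("X and A disagree on the number of spots")
    dH = H - X
    dA = A_rec - A
    return _maybe_float((alpha1 * tsum(dH * dH) + alpha2 * tsum(dA * dA)) / n)


# --------------------------------------------------------- local contrastive


def local_contrastive_loss(P: Any, P_hat: Any, A: Any, tau: float = 0.5) -> Any:
    """Neighborhood-aware InfoNCE over both views, averaged over anchors."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    Pd, Qd = asdata(P), asdata(P_hat)
    if Pd.shape != Qd.shape:
        raise ValueError("P and P_hat must share shape")
    A = np.asarray(asdata(A), dtype=np.float64)
    n = Pd.shape[0]
    if A.shape != (n, n):
        raise ValueError(f"A shape {A.shape} does not match {n} spots")
    A = A.copy()
    np.fill_diagonal(A, 0.0)  # neighborhood sets never include the anchor itself

    Pn = _row_l2_normalize(P)
    Qn = _row_l2_normalize(P_hat)
    C11 = Pn @ Pn.T
    C12 = Pn @ Qn.T
    C22 = Qn @ Qn.T

    n_hat = 2.0 * A.sum(axis=1) + 1.0  # positives per anchor
    mask_inter = A + np.eye(n)  # positives in the other view include the twin
    offdiag = 1.0 - np.eye(n)
    log_n_hat = np.log(n_hat)

    def anchor_loss(C_intra: Any, C_inter: Any) -> Any:
        # log-sum-exp with separate per-anchor shifts for the numerator
        # (max over positive candidates) and denominator (max over all
        # candidates), both detached; exponents in the numerator are masked
        # before exponentiation so out-of-set entries cannot overflow
        Ci, Ce = asdata(C_intra), asdata(C_inter)
        # the anchor itself is not a candidate: exclude Ci's diagonal (its
        # cosine is 1, which would otherwise dominate the shift and let the
        # true candidates underflow at small tau)
        Ci_off = Ci - np.diag(np.full(n, np.inf))
        m_den = np.maximum(Ci_off.max(axis=1), Ce.max(axis=1))[:, None] / tau
        m_num = (
            np.maximum(
                np.where(mask_inter > 0, Ce, -np.inf).max(axis=1),
                np.where(A > 0, Ci, -np.inf).max(axis=1, initial=-np.inf),
            )[:, None]
            / tau
        )
        E_intra = exp((C_intra * (1.0 / tau) - m_den) * offdiag) * offdiag
        E_inter = exp(C_inter * (1.0 / tau) - m_den)
        den = tsum(E_intra + E_inter, axis=1)
        gap = (m_den - m_num).ravel()
        if gap.max() < 600.0:
            # the numerator's own maximum is within floating-point range of
            # the denominator shift: reuse the exponentials with a per-row
            # rescale instead of exponentiating twice
            pos = tsum(E_intra * A + E_inter * mask_inter, axis=1) * np.exp(gap)
        else:
            E_num = exp((C_intra * (1.0 / tau) - m_num) * A) * A + exp(
                (C_inter * (1.0 / tau) - m_num) * mask_inter
            ) * mask_inter
            pos = tsum(E_num, axis=1)
        return (log(den) + m_den.ravel()) - (log(pos) + m_num.ravel()) + log_n_hat

    l_u = anchor_loss(C11, C12)
    l_v = anchor_loss(C22, C12.T)
    return _maybe_float(tsum(l_u + l_v) / (2.0 * n))


# -------------------------------------------------------- global contrastive


def readout(M: Any, A: Any) -> Any:
    """Degree-normalized neighborhood aggregation, L2-normalized, squashed.

    R = sigmoid(l2norm_rows((A M) / rowsums(A))).  Every node needs at
    least one neighbor; KNN construction guarantees that.
    """
    A = asdata(A)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("readout needs every node to have degree >= 1")
    if asdata(M).shape[0] != A.shape[0]:
        raise ValueError("M rows must match A")
    Y = matmul(A, M) * (1.0 / deg)[:, None]
    return sigmoid(_row_l2_normalize(Y))


def cross_view_similarity(R1: Any, R2: Any) -> Any:
    """Cosine similarity between feature dimensions of the two readouts.

    S_ij compares column i of R1 with column j of R2; zero-norm columns
    give 0 entries.
    """
    if asdata(R1).shape != asdata(R2).shape:
        raise ValueError("R1 and R2 must share shape")
    return _col_l2_normalize(R1).T @ _col_l2_normalize(R2)


def global_contrastive_loss(S: Any) -> Any:
    """Mean squared deviation of S from the identity."""
    if isinstance(S, SimilarityMatrix):
        S = S.S
    Sd = asdata(S)
    if Sd.ndim != 2 or Sd.shape[0] != Sd.shape[1]:
        raise ValueError("S must be square")
    d = Sd.shape[0]
    diff = S - np.eye(d)
    return _maybe_float(tsum(diff * diff) / (d * d))


# ----------------------------------------------------------------- combined


def total_loss(
    l_rec: float,
    l_loc: float,
    l_glo: float,
    alpha: float = 10.0,
    beta: float = 0.5,
    gamma: float = 0.5,
) -> LossBreakdown:
    """Weighted sum of the three objectives, with the breakdown retained."""
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    l_rec, l_loc, l_glo = float(l_rec), float(l_loc), float(l_glo)
    return LossBreakdown(
        l_rec=l_rec,
        l_loc=l_loc,
        l_glo=l_glo,
        total=alpha * l_rec + beta * l_loc + gamma * l_glo,
    )
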