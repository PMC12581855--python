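"""Independent brute-force oracles for the contrastive objectives.

These transcribe the loss definitions literally — explicit Python loops
over (anchor, candidate, view) triples with scalar cosine similarities —
and share no code with the vectorized implementations they check.
"""

import numpy as np


def _cos(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0  # cosine of a zero vector is defined as neutral
    return float(a @ b) / (na * nb)


def neighborhood_infonce_bruteforce(P, P_hat, A, tau):
    """Literal transcription of the neighborhood-aware contrastive loss.

    For anchor u_i: positives are v_i, the neighbors u_j, and the
    neighbors' twins v_j; the numerator averages their exponentiated
    similarities over the positive count; the denominator is the twin term
    plus every intra- and inter-view candidate j != i.  Symmetrized over
    both views and averaged.
    """
    P, P_hat, A = np.asarray(P), np.asarray(P_hat), np.asarray(A)
    n = P.shape[0]

    def f(a, b):
        return np.exp(_cos(a, b) / tau)

    def anchor_loss(view_a, view_b, i):
        nbrs = [j for j in range(n) if A[i, j] and j != i]
        num = f(view_a[i], view_b[i])
        for j in nbrs:
            num += f(view_a[i], view_a[j])  # intra-view neighbor positives
        for j in nbrs:
            num += f(view_a[i], view_b[j])  # inter-view neighbor positives
        n_hat = 2 * len(nbrs) + 1
        den = f(view_a[i], view_b[i])
        for j in range(n):
            if j != i:
                den += f(view_a[i], view_a[j]) + f(view_a[i], view_b[j])
        return -np.log((num / n_hat) / den)

    total = 0.0
    for i in range(n):
        total += anchor_loss(P, P_hat, i) + anchor_loss(P_hat, P, i)
    return total / (2 * n)


def classic_infonce_bruteforce(P, P_hat, tau):
    """The classical two-view InfoNCE: the only positive is the twin."""
    P, P_hat = np.asarray(P), np.asarray(P_hat)
    n = P.shape[0]

    def f(a, b):
        return np.exp(_cos(a, b) / tau)

    def anchor_loss(view_a, view_b, i):
        num = f(view_a[i], view_b[i])
        den = f(view_a[i], view_b[i])
        for k in range(n):
            if k != i:
                den += f(view_a[i], view_b[k])  # inter-view negatives
                den += f(view_a[i], view_a[k])  # intra-view negatives
        return -np.log(num / den)

    total = 0.0
    for i in range(n):
        total += anchor_loss(P, P_hat, i) + anchor_loss(P_hat, P, i)
    return total / (2 * n)


def random_knn_adjacency(rng, n, k):
    """A random symmetric KNN-style binary adjacency with zero diagonal."""
    coords = rng.normal(size=(n, 2))
    d = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d, np.inf)
    A = np.zeros((n, n))
    for i in range(n):
        A[i, np.argsort(d[i])[:k]] = 1.0
    return np.maximum(A, A.T)
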