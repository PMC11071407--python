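"""Morphology-constrained topic-model deconvolution of ST spots.

The reference expression matrix V (genes x cells, restricted to a balanced
marker panel) is factored as V = W H by seeded non-negative matrix
factorization in which topics are identified with cell types: W is
initialized from per-gene marker probabilities and H from the binary
cell-to-type assignment.  Spot profiles are then mapped onto the fixed topic
basis by non-negative least squares, topic signatures are summarized per type
by the median (Q), and per-spot compositions P solve

    min_{P >= 0}  ||H' - Q P||_F^2  +  alpha * ||L - S P||_F^2,

where L holds histology-derived superclass compositions, S maps
transcriptomic types onto superclasses, and alpha trades expression fit
against morphological agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .reference import NORMALIZE_TARGET, MarkerSet

logger = logging.getLogger(__name__)


@dataclass
class TopicModel:
    W: np.ndarray            # genes x topics
    H: np.ndarray            # topics x cells
    Q: Optional[np.ndarray]  # topics x k_sn consensus signatures
    gene_ids: list
    celltypes: list

    def __post_init__(self):
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("topic factors must be nonnegative")
        if self.W.shape[1] != len(self.celltypes):
            raise ValueError("number of topics must equal number of cell types")


@dataclass
class DeconvolutionResult:
    H_prime: np.ndarray      # topics x spots
    P: np.ndarray            # k_sn x spots
    alpha: float
    loss_trace: np.ndarray
    degenerate_spots: np.ndarray  # spots whose P column was all-zero pre-normalization


def preprocess(counts: np.ndarray, scale_sd: Optional[np.ndarray] = None):
    """Depth-normalize to 10k per column and scale genes to unit variance.

    Scaling divides by the gene SD without centering, so the matrix stays
    nonnegative.  Pass ``scale_sd`` to reuse the reference's gene scaling when
    preprocessing spot data, so both modalities live in the same space.
    Returns ``(matrix, scale_sd)``.
    """
    counts = np.asarray(counts, dtype=float)
    if not np.all(np.isfinite(counts)):
        raise ValueError("counts contain non-finite entries")
    depth = counts.sum(axis=0)
    x = counts / np.where(depth > 0, depth, 1.0) * NORMALIZE_TARGET
    if scale_sd is None:
        scale_sd = x.std(axis=1, ddof=0)
    x = x / np.where(scale_sd > 0, scale_sd, 1.0)[:, None]
    return x, scale_sd


def marker_init_W(markers: MarkerSet, gene_ids: list, celltypes: list, floor: float = 1e-6) -> np.ndarray:
    """Seed W[g, t] with the probability that gene g marks type t.

    Quantified as 1 - adjusted p-value of the marker test, floored so no
    entry is absorbing under multiplicative updates.
    """
    W = np.full((len(gene_ids), len(celltypes)), floor)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tidx = {t: i for i, t in enumerate(celltypes)}
    for row in markers.scores.itertuples():
        if row.gene in gidx and row.cell_type in tidx:
            W[gidx[row.gene], tidx[row.cell_type]] = max(1.0 - row.p_adj, floor)
    return W


def factorize_reference(
    V: np.ndarray,
    markers: MarkerSet,
    labels: np.ndarray,
    seed: int = 0,
    gene_ids: Optional[list] = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    W_init: Optional[np.ndarray] = None,
    H_init: Optional[np.ndarray] = None,
) -> TopicModel:
    """Seeded NMF of the (preprocessed, marker-restricted) reference.

    Multiplicative Frobenius updates; W is seeded from marker probabilities
    and H from the binary cell-type assignment, biasing topics toward cell
    types.  The reconstruction error is non-increasing over iterations.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V contains non-finite entries")
    labels = np.asarray(labels)
    _, order = np.unique(labels, return_index=True)
    celltypes = [str(t) for t in labels[np.sort(order)]]
    k = len(celltypes)
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = list(range(V.shape[0]))
    W = marker_init_W(markers, gene_ids, celltypes) if W_init is None else np.array(W_init, dtype=float)
    if H_init is None:
        H = np.zeros((k, V.shape[1]))
        for t_i, t in enumerate(celltypes):
            H[t_i, labels.astype(str) == t] = 1.0
    else:
        H = np.array(H_init, dtype=float)
    # tiny seeded jitter keeps exact-zero rows from locking the factorization
    W = W + rng.uniform(0, 1e-10, W.shape)
    eps = 1e-12
    err_prev = np.inf
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        if it % 10 == 0 or it == max_iter - 1:
            err = np.linalg.norm(V - W @ H)
            if err_prev - err < tol * max(err_prev, 1.0):
                break
            err_prev = err
    return TopicModel(W=W, H=H, Q=None, gene_ids=list(gene_ids), celltypes=celltypes)


def map_spots_to_topics(V_prime: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve V' ~= W H' for H' >= 0, one NNLS problem per spot column."""
    V_prime = np.asarray(V_prime, dtype=float)
    if V_prime.shape[0] != W.shape[0]:
        raise ValueError(
            f"gene-space mismatch: V' has {V_prime.shape[0]} genes, W has {W.shape[0]}"
        )
    H_prime = np.empty((W.shape[1], V_prime.shape[1]))
    for s in range(V_prime.shape[1]):
        H_prime[:, s] = nnls(W, V_prime[:, s])[0]
    return H_prime


def consensus_topics(H: np.ndarray, labels: np.ndarray, celltypes: Optional[list] = None) -> np.ndarray:
    """Median topic weight per cell type: the consensus signature Q."""
    labels = np.asarray(labels).astype(str)
    if celltypes is None:
        _, order = np.unique(labels, return_index=True)
        celltypes = labels[np.sort(order)].tolist()
    Q = np.empty((H.shape[0], len(celltypes)))
    for c, t in enumerate(celltypes):
        members = labels == str(t)
        if not members.any():
            raise ValueError(f"cell type {t!r} has no cells")
        Q[:, c] = np.median(H[:, members], axis=1)
    return Q


def _adam_minimize(grad_fn, loss_fn, x0, lr, n_iter, trace_every=100):
    """Projected (x >= 0) Adam descent; returns (x, loss_trace)."""
    x = x0.copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace = []
    for t in range(1, n_iter + 1):
        g = grad_fn(x)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        x = np.maximum(x - lr * mhat / (np.sqrt(vhat) + eps), 0.0)
        if t % trace_every == 0 or t == n_iter:
            trace.append(loss_fn(x))
    return x, np.asarray(trace)


def infer_compositions(
    H_prime: np.ndarray,
    Q: np.ndarray,
    L: Optional[np.ndarray] = None,
    S: Optional[np.ndarray] = None,
    alpha: float = 0.0,
    seed: int = 0,
    lr: float = 0.01,
    n_iter: int = 100_000,
    normalize: bool = True,
    zero_morphology: str = "unconstrained",
) -> DeconvolutionResult:
    """Morphology-constrained composition inference (first-order descent).

    Minimizes ``||H' - Q P||_F^2 + alpha ||L - S P||_F^2`` over P >= 0 with
    Adam (learning rate 0.01, 100k iterations by default) from a seeded
    random initialization.  With ``alpha = 0`` the solution coincides with
    per-spot NNLS of H' on Q.  ``normalize`` renormalizes each spot column of
    P to a simplex (all-zero columns map to the uniform simplex and are
    flagged).  Spots whose morphology column of L is all zero are either
    deconvolved without the morphology term (``zero_morphology =
    'unconstrained'``) or dropped from the morphology loss entirely
    (``'drop'`` behaves identically here since the term is already zero).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    H_prime = np.asarray(H_prime, dtype=float)
    Q = np.asarray(Q, dtype=float)
    k_sn, n_spots = Q.shape[1], H_prime.shape[1]
    use_morph = alpha > 0 and L is not None
    if use_morph:
        L = np.asarray(L, dtype=float)
        S = np.asarray(S, dtype=float)
        if S.shape != (L.shape[0], k_sn):
            raise ValueError(
                f"superclass map S {S.shape} inconsistent with L ({L.shape[0]} superclasses) "
                f"and Q ({k_sn} cell types)"
            )
        if L.shape[1] != n_spots:
            raise ValueError("L must have one column per spot")
        morph_w = np.ones(n_spots)
        empty = L.sum(axis=0) == 0
        if empty.any() and zero_morphology in ("unconstrained", "drop"):
            morph_w[empty] = 0.0

    QtQ, QtH = Q.T @ Q, Q.T @ H_prime
    if use_morph:
        StS, StL = S.T @ S, S.T @ L

    def grad(P):
        g = 2.0 * (QtQ @ P - QtH)
        if use_morph:
            g = g + 2.0 * alpha * ((StS @ P - StL) * morph_w)
        return g

    def loss(P):
        val = np.linalg.norm(H_prime - Q @ P) ** 2
        if use_morph:
            val += alpha * np.linalg.norm((L - S @ P) * morph_w) ** 2
        return val

    rng = np.random.default_rng(seed)
    P0 = rng.uniform(0, 1, (k_sn, n_spots))
    P, trace = _adam_minimize(grad, loss, P0, lr, n_iter)
    degenerate = P.sum(axis=0) <= 0
    if normalize:
        tot = P.sum(axis=0)
        P = np.where(tot > 0, P / np.where(tot > 0, tot, 1.0), 1.0 / k_sn)
        if degenerate.any():
            logger.warning("%d spot(s) had all-zero compositions; set to uniform", int(degenerate.sum()))
    return DeconvolutionResult(H_prime=H_prime, P=P, alpha=alpha, loss_trace=trace, degenerate_spots=degenerate)


def stacked_nnls_compositions(H_prime, Q, L=None, S=None, alpha: float = 0.0) -> np.ndarray:
    """Exact solution of the morphology-constrained objective via NNLS.

    Stacks [Q; sqrt(alpha) S] against [H'; sqrt(alpha) L]; used as an
    independent check on the iterative path.
    """
    if alpha > 0 and L is not None:
        A = np.vstack([Q, np.sqrt(alpha) * S])
        B = np.vstack([H_prime, np.sqrt(alpha) * L])
    else:
        A, B = np.asarray(Q, float), np.asarray(H_prime, float)
    P = np.empty((A.shape[1], B.shape[1]))
    for s in range(B.shape[1]):
        P[:, s] = nnls(A, B[:, s])[0]
    return P
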