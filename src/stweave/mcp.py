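"""Multicellular program (MCP) discovery by sparse multi-CCA.

Given posterior-mean cellular expression matrices {beta_1, ..., beta_k}
(genes x conditions, one per cell type present in a spatial niche), find
sparse canonical variates w_1..w_k maximizing the sum of pairwise
cross-products

    sum_{i<j} w_i^T beta_i beta_j^T w_j,   ||w_i||_2 <= 1, ||w_i||_1 < c_i,

the penalized-matrix-decomposition form of multi-set CCA.  Each program's
member genes are the strongest contributors (|w| > 0.1, at most 250 genes
across all types, signed up/down); programs with incoherent members (low
self-correlation) or redundant with earlier programs (high
cross-correlation) are filtered; activity per condition is the weighted sum
of member-gene expression; membership lists feed a Fisher-exact gene-set
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

WEIGHT_THRESHOLD = 0.1
MAX_GENES_PER_PROGRAM = 250
MIN_SELF_CORR = 0.3
MAX_CROSS_CORR = 0.05


@dataclass
class MCPInput:
    """Per-cell-type posterior-mean expression over a shared condition axis."""

    beta_bar: list          # k matrices, each (n_genes_i, n_conditions)
    included_types: list
    included_genes: list    # per-type gene id lists
    conditions: list

    def __post_init__(self):
        if len(self.beta_bar) < 2:
            raise ValueError("MCP analysis needs at least 2 cell types")
        n_cond = {b.shape[1] for b in self.beta_bar}
        if len(n_cond) != 1:
            raise ValueError("all matrices must share the condition axis")


@dataclass
class MCPModel:
    variates: list          # per program: list of k weight vectors
    penalties: list
    types: list
    gene_lists: list        # per-type gene ids aligned with weights
    objective: list         # per program PMD objective
    gene_sets: list = field(default_factory=list)   # filled by extract_mcp_genes
    activity: Optional[np.ndarray] = None
    kept: Optional[np.ndarray] = None

    @property
    def n_programs(self) -> int:
        return len(self.variates)


def select_mcp_features(
    beta_bar: dict,
    compositions: np.ndarray,
    celltypes: Sequence[str],
    gene_ids: Sequence[str],
    conditions: Sequence,
    min_type_frac: float = 0.05,
    top_gene_frac: float = 0.05,
    cv_eps: float = 1e-8,
) -> MCPInput:
    """Choose the cell types and genes entering MCP discovery for one niche.

    Types with mean spot fraction below ``min_type_frac`` are excluded (their
    posterior rates are too uncertain); per surviving type the top
    ``top_gene_frac`` of genes by coefficient of variation of exp(beta-bar)
    across conditions are retained.  The CV is computed on the natural
    (exponentiated) scale with an epsilon floor on the mean, since the log
    rates can be near zero-mean.
    """
    comp = np.asarray(compositions, dtype=float)
    mean_frac = comp.mean(axis=0)
    keep_types = [i for i, f in enumerate(mean_frac) if f >= min_type_frac]
    if len(keep_types) < 2:
        raise ValueError(
            f"fewer than 2 cell types at mean spot fraction >= {min_type_frac}; cannot run MCP analysis"
        )
    mats, types, genes = [], [], []
    for i in keep_types:
        t = celltypes[i]
        B = np.asarray(beta_bar[t], dtype=float)  # genes x conditions
        expB = np.exp(B)
        cv = expB.std(axis=1, ddof=0) / np.maximum(expB.mean(axis=1), cv_eps)
        n_top = max(int(np.ceil(top_gene_frac * len(cv))), 1)
        top = np.argsort(-cv, kind="stable")[:n_top]
        top = np.sort(top)
        mats.append(B[top])
        types.append(t)
        genes.append([gene_ids[g] for g in top])
    return MCPInput(beta_bar=mats, included_types=types, included_genes=genes,
                    conditions=list(conditions))


def _soft(x: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _sparse_unit(x: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold + L2-normalize so that ||w||_2 = 1 and ||w||_1 <= c."""
    nrm = np.linalg.norm(x)
    if nrm == 0:
        return x
    w = x / nrm
    if np.linalg.norm(w, 1) <= c:
        return w
    lo, hi = 0.0, np.abs(x).max()
    for _ in range(80):
        mid = (lo + hi) / 2
        w = _soft(x, mid)
        nw = np.linalg.norm(w)
        if nw == 0:
            hi = mid
            continue
        if np.linalg.norm(w / nw, 1) > c:
            lo = mid
        else:
            hi = mid
    w = _soft(x, hi)
    nw = np.linalg.norm(w)
    return w / nw if nw > 0 else w


def _standardize(mats: list) -> list:
    out = []
    for B in mats:
        mu = B.mean(axis=1, keepdims=True)
        sd = B.std(axis=1, ddof=0, keepdims=True)
        out.append((B - mu) / np.where(sd > 0, sd, 1.0))
    return out


def _pmd_objective(mats: list, ws: list) -> float:
    k = len(mats)
    val = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            val += float(ws[i] @ mats[i] @ mats[j].T @ ws[j])
    return val


def _sign_fix(u: np.ndarray) -> np.ndarray:
    return -u if u[np.argmax(np.abs(u))] < 0 else u


def _pmd_iterate(mats: list, cs: list, ws: list, max_iter: int = 200, tol: float = 1e-8):
    prev = -np.inf
    for _ in range(max_iter):
        for i in range(len(mats)):
            target = np.zeros(mats[i].shape[0])
            for j in range(len(mats)):
                if j != i:
                    target += mats[i] @ (mats[j].T @ ws[j])
            if np.linalg.norm(target) > 0:
                ws[i] = _sparse_unit(target, cs[i])
        obj = _pmd_objective(mats, ws)
        if obj - prev < tol * max(abs(prev), 1.0):
            break
        prev = obj
    return ws, obj


def _pmd_one(mats: list, cs: list, seed: int, max_iter: int = 200, tol: float = 1e-8):
    """One sparse program: alternating soft-thresholded power iterations.

    The sparse problem is non-convex, so a deterministic multi-start is used:
    per-matrix leading singular vectors, plus for every ordered pair the
    singular pair of their cross-product; the start reaching the best
    objective wins.
    """
    k = len(mats)
    own = [_sign_fix(np.linalg.svd(B, full_matrices=False)[0][:, 0]) for B in mats]
    starts = [list(own)]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            # keep the pair's relative sign: u1' M v1 = sigma_1 > 0
            U, _, Vt = np.linalg.svd(mats[i] @ mats[j].T)
            cand = list(own)
            cand[i] = U[:, 0]
            cand[j] = Vt[0]
            starts.append(cand)
    best_ws, best_obj = None, -np.inf
    for start in starts:
        ws = [_sparse_unit(w.copy(), c) for w, c in zip(start, cs)]
        ws, obj = _pmd_iterate(mats, cs, ws, max_iter=max_iter, tol=tol)
        if obj > best_obj:
            best_ws, best_obj = ws, obj
    return best_ws, best_obj


def permutation_penalties(
    mats: list,
    grid: Sequence[float] = (1.1, 1.5, 2.0, 3.0, 4.0),
    n_permutations: int = 25,
    seed: int = 0,
) -> list:
    """Choose sparsity penalties by comparing against condition permutations.

    For each candidate factor f (c_i = f * sqrt(p_i), clipped to valid
    range), fit the first program on the real matrices and on
    ``n_permutations`` column-permuted copies; pick the factor with the
    largest standardized gap between real and permuted objectives.
    """
    rng = np.random.default_rng(seed)
    mats = _standardize(mats)
    best, best_z = None, -np.inf
    for f in grid:
        cs = [min(max(f, 1.0 + 1e-6), np.sqrt(B.shape[0])) for B in mats]
        _, obj = _pmd_one(mats, cs, seed)
        perm_objs = []
        for p in range(n_permutations):
            pm = [B[:, rng.permutation(B.shape[1])] for B in mats]
            perm_objs.append(_pmd_one(pm, cs, seed)[1])
        mu, sd = np.mean(perm_objs), np.std(perm_objs) + 1e-12
        z = (obj - mu) / sd
        if z > best_z:
            best_z, best = z, cs
    return best


def pmd_multicca(
    mcp_input: MCPInput,
    penalties: Optional[Sequence[float]] = None,
    n_programs: Optional[int] = None,
    seed: int = 0,
) -> MCPModel:
    """Sparse multi-CCA by alternating soft-thresholded power iterations.

    Matrices are standardized gene-wise across conditions.  Each successive
    program is found after deflating every matrix against its previous
    variates, so within-type bases are orthogonal.  When ``penalties`` is
    omitted they are chosen by the permutation approach.
    """
    mats = _standardize([np.asarray(B, dtype=float) for B in mcp_input.beta_bar])
    k = len(mats)
    if penalties is None:
        penalties = permutation_penalties(mats, seed=seed)
    penalties = list(penalties)
    for c in penalties:
        if c < 1:
            raise ValueError("penalties c_i must be >= 1 (unit-norm vectors have L1 norm >= 1)")
    n_programs = k if n_programs is None else min(n_programs, k)
    work = [B.copy() for B in mats]
    variates, objectives = [], []
    for m in range(n_programs):
        ws, obj = _pmd_one(work, penalties, seed + m)
        variates.append([w.copy() for w in ws])
        objectives.append(obj)
        # deflate each matrix against its variate: project out the gene-space component
        for i in range(k):
            w = ws[i]
            if np.linalg.norm(w) > 0:
                work[i] = work[i] - np.outer(w, w @ work[i])
    return MCPModel(
        variates=variates, penalties=penalties, types=list(mcp_input.included_types),
        gene_lists=[list(g) for g in mcp_input.included_genes], objective=objectives,
    )


def extract_mcp_genes(model: MCPModel,
                      weight_threshold: float = WEIGHT_THRESHOLD,
                      max_genes: int = MAX_GENES_PER_PROGRAM) -> list:
    """Signed member-gene sets per program.

    Keeps genes with |w| above threshold, ranked by |w| across all cell
    types, capped at ``max_genes`` per program; positive weights are the
    "up" set, negative the "down" set.  Stored on the model and returned.
    """
    out = []
    for ws in model.variates:
        rows = []
        for t, w, genes in zip(model.types, ws, model.gene_lists):
            for g_idx in np.flatnonzero(np.abs(w) > weight_threshold):
                rows.append((model.types.index(t), t, genes[g_idx], g_idx, w[g_idx]))
        rows.sort(key=lambda r: -abs(r[4]))
        rows = rows[:max_genes]
        out.append({
            "up": [(t, g, w) for _, t, g, _, w in rows if w > 0],
            "down": [(t, g, w) for _, t, g, _, w in rows if w < 0],
            "members": [(t, g, gi, w) for _, t, g, gi, w in rows],
        })
    model.gene_sets = out
    return out


def filter_programs(model: MCPModel, mcp_input: MCPInput,
                    min_self_corr: float = MIN_SELF_CORR,
                    max_cross_corr: float = MAX_CROSS_CORR) -> np.ndarray:
    """Drop incoherent or redundant programs.

    Every program must be internally coherent: the mean pairwise Pearson
    correlation of its member-gene signals across conditions (with "down"
    members sign-flipped) must reach ``min_self_corr``.  Since multi-CCA
    always emits programs in the same order, redundancy is judged against
    earlier output only: a latter program is also dropped when its members'
    mean absolute correlation with any earlier kept program's members
    exceeds ``max_cross_corr``.  The first program has no comparators, which
    is logged.
    """
    if not model.gene_sets:
        extract_mcp_genes(model)
    mats = _standardize([np.asarray(B, dtype=float) for B in mcp_input.beta_bar])
    tindex = {t: i for i, t in enumerate(model.types)}

    def member_signals(prog):
        sig = []
        for t, g, g_idx, w in prog["members"]:
            sig.append(np.sign(w) * mats[tindex[t]][g_idx])
        return np.asarray(sig)

    signals = [member_signals(p) for p in model.gene_sets]
    kept = np.ones(model.n_programs, dtype=bool)
    for m, sig in enumerate(signals):
        if sig.shape[0] < 2:
            kept[m] = False
            continue
        C = np.corrcoef(sig)
        iu = np.triu_indices_from(C, k=1)
        self_r = np.nanmean(C[iu])
        if self_r < min_self_corr:
            kept[m] = False
            continue
        earlier = [signals[o] for o in range(m) if kept[o] and signals[o].shape[0] > 0]
        if not earlier:
            logger.info("program %d: no earlier programs; cross-correlation test skipped", m)
            continue
        cross = []
        for o in earlier:
            full = np.corrcoef(np.vstack([sig, o]))
            cross.append(np.nanmean(np.abs(full[: sig.shape[0], sig.shape[0]:])))
        if np.mean(cross) > max_cross_corr:
            kept[m] = False
    model.kept = kept
    return kept


def mcp_activity(model: MCPModel, mcp_input: MCPInput) -> np.ndarray:
    """Activity per condition: y_m = sum_i sum_g beta_i[g, :] * w_i[g, m].

    Linear in beta-bar.  Returns (n_programs, n_conditions); per-type
    contributions are recoverable by restricting the sum to one type.
    """
    n_cond = mcp_input.beta_bar[0].shape[1]
    act = np.zeros((model.n_programs, n_cond))
    for m, ws in enumerate(model.variates):
        for B, w in zip(mcp_input.beta_bar, ws):
            act[m] += w @ np.asarray(B, dtype=float)
    model.activity = act
    return act


def mcp_cellular_contributions(model: MCPModel, mcp_input: MCPInput) -> pd.DataFrame:
    """Signed per-type weight mass per program (positive vs negative bins)."""
    rows = []
    for m, ws in enumerate(model.variates):
        for t, w in zip(model.types, ws):
            rows.append((m, t, float(w[w > 0].sum()), float(w[w < 0].sum())))
    return pd.DataFrame(rows, columns=["program", "cell_type", "positive", "negative"])


def enrich_fisher(genes: set, universe: set, gene_sets: dict) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a query set against collections.

    Builds the 2x2 membership table per named set (restricted to the
    universe) and BH-adjusts across sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    genes = set(genes)
    if not genes <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    universe = set(universe)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        a = len(genes & members)
        b = len(genes - members)
        c = len(members - genes)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), p))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def read_gmt(path: str) -> dict:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets
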