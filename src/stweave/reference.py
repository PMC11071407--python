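"""Cell-typed single-nucleus/cell reference: marker genes and empirical priors.

The reference arrives pre-labeled (one cell type per cell) together with a
map from each transcriptomic type to one coarse morphological superclass.
From it we derive (a) a balanced marker-gene panel used to seed deconvolution
and (b) per-(region, cell type, gene) empirical normal priors that anchor the
hierarchical expression model in compositional mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NORMALIZE_TARGET = 1e4  # depth-normalize to 10k counts per cell


class PriorMode(str, Enum):
    compositional = "compositional"
    non_compositional = "non_compositional"


@dataclass
class ReferenceProfiles:
    """Genes x cells reference counts with one type label per cell.

    ``superclass_map`` is a binary (k_morph x k_sn) matrix S assigning each
    transcriptomic type to exactly one morphological superclass.
    """

    counts: np.ndarray
    gene_ids: list
    cell_type: np.ndarray
    superclass_map: Optional[np.ndarray] = None
    superclasses: Optional[list] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_type = np.asarray(self.cell_type)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match counts rows")
        if self.counts.shape[1] != len(self.cell_type):
            raise ValueError("cell_type length does not match counts columns")
        if np.any(self.counts < 0):
            raise ValueError("reference counts must be nonnegative")
        if self.superclass_map is not None:
            S = np.asarray(self.superclass_map)
            if not np.array_equal(S.sum(axis=0), np.ones(S.shape[1])):
                raise ValueError("each cell type must map to exactly one superclass")
            self.superclass_map = S

    @property
    def types(self) -> np.ndarray:
        """Unique cell types in first-appearance order."""
        _, order = np.unique(self.cell_type, return_index=True)
        return self.cell_type[np.sort(order)]

    def type_profiles(self) -> pd.DataFrame:
        """Mean raw count per gene per type (genes x types)."""
        out = {t: self.counts[:, self.cell_type == t].mean(axis=1) for t in self.types}
        return pd.DataFrame(out, index=self.gene_ids)


@dataclass
class ReferencePriors:
    """Per-(MROI, cell type, gene) normal prior hyperparameters for beta.

    mu / sigma are (n_genes, n_mrois, n_types) arrays; in non-compositional
    mode the type axis has length 1 and (mu, sigma) = (0, 2) everywhere.
    """

    mu: np.ndarray
    sigma: np.ndarray
    gene_ids: list
    mrois: list
    celltypes: list
    mode: PriorMode

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("prior sigma must be positive everywhere")
        if self.mode == PriorMode.non_compositional:
            if not (np.all(self.mu == 0) and np.all(self.sigma == 2)):
                raise ValueError("non-compositional priors must be N(0, 2^2)")

    def for_gene(self, gene_index: int) -> tuple[np.ndarray, np.ndarray]:
        return self.mu[gene_index], self.sigma[gene_index]


@dataclass
class MarkerSet:
    """Balanced per-type marker panel: m genes per type, deduplicated union."""

    genes: list
    per_type: dict
    scores: pd.DataFrame  # columns: gene, cell_type, p_adj, log2fc
    m: int


def _normalize_depth(counts: np.ndarray, target: float = NORMALIZE_TARGET) -> np.ndarray:
    depth = counts.sum(axis=0)
    depth = np.where(depth > 0, depth, 1.0)
    return counts / depth * target


def empirical_priors(
    ref: ReferenceProfiles,
    mroi_set: Sequence,
    mode: PriorMode | str = PriorMode.compositional,
    sigma_floor: float = 0.1,
    pseudocount: float = 1.0,
) -> ReferencePriors:
    """Empirical normal priors for the characteristic expression rates.

    Compositional mode: per cell type, the mean and sample SD of
    ``log(pseudocount + depth-normalized expression)`` over that type's
    cells, replicated across all MROIs (SD floored at ``sigma_floor`` so a
    constant gene cannot produce a degenerate zero-width prior).
    Non-compositional mode ignores the reference and returns N(0, 2^2)
    everywhere.
    """
    mode = PriorMode(mode)
    mrois = list(mroi_set)
    n_genes = len(ref.gene_ids)
    if mode == PriorMode.non_compositional:
        shape = (n_genes, len(mrois), 1)
        return ReferencePriors(
            mu=np.zeros(shape), sigma=np.full(shape, 2.0),
            gene_ids=list(ref.gene_ids), mrois=mrois, celltypes=["average"], mode=mode,
        )
    types = list(ref.types)
    for t in types:
        if (ref.cell_type == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells; cannot form empirical priors")
    logx = np.log(pseudocount + _normalize_depth(ref.counts))
    mu_t = np.empty((n_genes, len(types)))
    sd_t = np.empty((n_genes, len(types)))
    for c, t in enumerate(types):
        sub = logx[:, ref.cell_type == t]
        mu_t[:, c] = sub.mean(axis=1)
        sd_t[:, c] = sub.std(axis=1, ddof=1)
    sd_t = np.maximum(sd_t, sigma_floor)
    mu = np.repeat(mu_t[:, None, :], len(mrois), axis=1)
    sigma = np.repeat(sd_t[:, None, :], len(mrois), axis=1)
    return ReferencePriors(
        mu=mu, sigma=sigma, gene_ids=list(ref.gene_ids),
        mrois=mrois, celltypes=[str(t) for t in types], mode=mode,
    )


def select_markers(
    ref: ReferenceProfiles,
    fdr: float = 0.05,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
    m: Optional[int] = None,
) -> MarkerSet:
    """Balanced marker selection by one-vs-rest Welch t-tests.

    Counts are depth-normalized to 10k per cell and gene-wise scaled to unit
    variance, then log(x + pseudocount) transformed.  Per type, each gene is
    tested one-vs-rest (Welch t); p-values are Benjamini-Hochberg adjusted
    across genes within the type.  Significant markers require adjusted
    p < ``fdr`` and log2 fold change > ``min_log2fc``.  The panel size m is
    the minimum significant-marker count across types (so the panel is
    balanced); the top m per type by adjusted p are retained, with ties broken
    by |log2fc| then gene id, and the deduplicated union returned.
    """
    types = list(ref.types)
    x = _normalize_depth(ref.counts)
    sd = x.std(axis=1, ddof=0)
    x = x / np.where(sd > 0, sd, 1.0)[:, None]
    logx = np.log(x + pseudocount)
    records = []
    n_sig = {}
    for t in types:
        in_t = ref.cell_type == t
        a, b = logx[:, in_t], logx[:, ~in_t]
        tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        # one-sided: markers are over-expressed in the type
        p_one = np.where(tstat > 0, p / 2, 1 - p / 2)
        p_adj = multipletests(p_one, method="fdr_bh")[1]
        lfc = (np.log(x[:, in_t].mean(axis=1) + pseudocount) - np.log(x[:, ~in_t].mean(axis=1) + pseudocount)) / np.log(2)
        sig = (p_adj < fdr) & (lfc > min_log2fc)
        n_sig[t] = int(sig.sum())
        for g_idx in np.flatnonzero(sig):
            records.append((ref.gene_ids[g_idx], t, p_adj[g_idx], lfc[g_idx]))
    zero = [t for t, n in n_sig.items() if n == 0]
    if zero:
        raise ValueError(
            f"no significant markers for type(s) {zero}; relax the fdr/min_log2fc thresholds"
        )
    scores = pd.DataFrame(records, columns=["gene", "cell_type", "p_adj", "log2fc"])
    m_eff = min(n_sig.values()) if m is None else min(m, min(n_sig.values()))
    per_type = {}
    for t in types:
        sub = scores[scores.cell_type == t].copy()
        sub["abs_lfc"] = sub.log2fc.abs()
        sub = sub.sort_values(["p_adj", "abs_lfc", "gene"], ascending=[True, False, True])
        per_type[t] = sub.gene.head(m_eff).tolist()
    union: list = []
    seen = set()
    for t in types:
        for g in per_type[t]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    logger.info("select_markers: m=%d per type, %d unique genes", m_eff, len(union))
    return MarkerSet(genes=union, per_type=per_type, scores=scores, m=m_eff)
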