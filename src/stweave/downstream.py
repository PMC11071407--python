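"""Composition statistics, crypt-gradient gene calling, and power analysis.

Composition comparisons treat each tissue section as one independent sample
(spot simplexes averaged per section per MROI) and use Welch's
unequal-variance t-test per cell type, BH-corrected across cell types
within an MROI.  Gradient genes combine a Bayes-factor DE call between the
crypt base and apex with a monotonicity requirement across the ordered
crypt compartments.  The power analysis quantifies information lost to
subsampled designs as the KL divergence between normal approximations of
full-data and subsampled posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SIGNIFICANCE_STARS = ((1e-4, "****"), (1e-3, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in SIGNIFICANCE_STARS:
        if p <= cut:
            return stars
    return ""


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sided t-test, written out in full.

    Returns (t, Welch-Satterthwaite df, p).  Kept independent of
    scipy.stats.ttest_ind so the two can cross-check each other.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class CompositionTest:
    section_means: pd.DataFrame   # one row per (section, mroi), simplex columns
    results: pd.DataFrame         # cell_type, mroi, group_a, group_b, t, df, p, p_adj, stars


def composition_welch(
    compositions: np.ndarray,
    sections: np.ndarray,
    mrois: np.ndarray,
    groups: np.ndarray,
    celltypes: Sequence[str],
) -> CompositionTest:
    """Group-wise composition comparison with sections as replicates.

    Spot simplexes are averaged per (section, MROI); per MROI and cell type
    every group pair is compared by Welch's t-test; p-values are
    BH-corrected across cell types within each (MROI, group pair) family.
    Group pairs where a side has fewer than 2 sections are skipped with a
    log line.
    """
    comp = np.asarray(compositions, dtype=float)
    df = pd.DataFrame(comp, columns=list(celltypes))
    df["section"] = np.asarray(sections)
    df["mroi"] = np.asarray(mrois)
    df["group"] = np.asarray(groups)
    section_means = (
        df.groupby(["section", "mroi", "group"], sort=True)[list(celltypes)].mean().reset_index()
    )
    rows = []
    for mroi in sorted(section_means.mroi.unique()):
        sub = section_means[section_means.mroi == mroi]
        group_names = sorted(sub.group.unique())
        for i, ga in enumerate(group_names):
            for gb in group_names[i + 1:]:
                xa = sub[sub.group == ga]
                xb = sub[sub.group == gb]
                if len(xa) < 2 or len(xb) < 2:
                    logger.info("mroi %s: %s vs %s skipped (needs >= 2 sections per group)", mroi, ga, gb)
                    continue
                fam = []
                for ct in celltypes:
                    t, dfree, p = welch_t(xa[ct].to_numpy(), xb[ct].to_numpy())
                    fam.append((ct, mroi, ga, gb, t, dfree, p))
                padj = multipletests([f[6] for f in fam], method="fdr_bh")[1]
                for f, pa in zip(fam, padj):
                    rows.append((*f, pa, significance_stars(pa)))
    results = pd.DataFrame(
        rows, columns=["cell_type", "mroi", "group_a", "group_b", "t", "df", "p", "p_adj", "stars"]
    )
    return CompositionTest(section_means=section_means, results=results)


CRYPT_ORDER = ["BASE", "BASE&MID", "MID", "APEX"]


def gradient_genes(
    de_results: pd.DataFrame,
    rate_means: pd.DataFrame,
    mroi_order: Sequence[str] = tuple(CRYPT_ORDER),
    bf_threshold: float = 2.0,
    lfc_threshold: float = 0.5,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Genes changing monotonically along the crypt base-to-apex axis.

    ``de_results`` holds the base-vs-apex call per gene (columns: gene, bf,
    lfc); ``rate_means`` holds posterior-mean log rates per gene with one
    column per crypt MROI in ``mroi_order``.  A gradient gene satisfies
    BF > ``bf_threshold`` and |log2 fc| > ``lfc_threshold`` AND is
    non-strictly monotone (tolerance ``tol``) across the ordered MROIs in
    the direction of the fold change.
    """
    missing = [m for m in mroi_order if m not in rate_means.columns]
    if missing:
        raise ValueError(f"rate_means is missing crypt MROIs: {missing}")
    out = []
    for row in de_results.itertuples():
        means = rate_means.loc[row.gene, list(mroi_order)].to_numpy(dtype=float)
        diffs = np.diff(means)
        if row.lfc > 0:
            # apex-high genes must rise base -> apex
            monotone = bool(np.all(diffs >= -tol)) and means[-1] > means[0]
        elif row.lfc < 0:
            monotone = bool(np.all(diffs <= tol)) and means[-1] < means[0]
        else:
            monotone = False
        is_gradient = (row.bf > bf_threshold) and (abs(row.lfc) > lfc_threshold) and monotone
        out.append((row.gene, row.bf, row.lfc, monotone, is_gradient))
    return (
        pd.DataFrame(out, columns=["gene", "bf", "lfc", "monotone", "is_gradient"])
        .sort_values("gene", kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class PosteriorKLD:
    table: pd.DataFrame  # gene, mean_full, sd_full, mean_sub, sd_sub, kld


def normal_kld(mu_p: float, sd_p: float, mu_q: float, sd_q: float) -> float:
    """KL(P || Q) between two univariate normals."""
    if sd_p <= 0 or sd_q <= 0:
        raise ValueError("posterior SDs must be positive (floor them upstream)")
    return float(
        np.log(sd_q / sd_p) + (sd_p**2 + (mu_p - mu_q) ** 2) / (2 * sd_q**2) - 0.5
    )


def posterior_kld(
    full_means: np.ndarray,
    full_sds: np.ndarray,
    sub_means: np.ndarray,
    sub_sds: np.ndarray,
    genes: Optional[Sequence[str]] = None,
) -> PosteriorKLD:
    """Information lost by subsampling: KLD(full || sub) per gene.

    Posteriors are summarized by normal approximations (posterior mean and
    SD); the divergence direction measures how much is lost when the
    subsampled posterior stands in for the full one.
    """
    full_means = np.asarray(full_means, dtype=float).ravel()
    full_sds = np.asarray(full_sds, dtype=float).ravel()
    sub_means = np.asarray(sub_means, dtype=float).ravel()
    sub_sds = np.asarray(sub_sds, dtype=float).ravel()
    if not (len(full_means) == len(full_sds) == len(sub_means) == len(sub_sds)):
        raise ValueError("full and subsampled summaries must be matched")
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(len(full_means))]
    kld = [
        normal_kld(mf, sf, ms, ss)
        for mf, sf, ms, ss in zip(full_means, full_sds, sub_means, sub_sds)
    ]
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_full": full_means,
            "sd_full": full_sds,
            "mean_sub": sub_means,
            "sd_sub": sub_sds,
            "kld": kld,
        }
    )
    return PosteriorKLD(table=table)
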