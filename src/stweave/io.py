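"""Readers and writers for the plain-text ST interchange formats.

Counts travel either as Matrix Market (.mtx) with sidecar ``features.tsv`` /
``barcodes.tsv`` files, or as a single genes x spots TSV.  Spot metadata is a
TSV with columns ``spot_id, tissue_id, x, y, mroi`` plus free covariate
columns; compositions are a CSV with one column per cell type whose rows sum
to one.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .spatial import STArray

SPOT_META_COLUMNS = ["spot_id", "tissue_id", "x", "y", "mroi"]


def read_counts_mtx(mtx_path: str, features_path: str, barcodes_path: str):
    """Read a genes x spots Matrix Market file with TSV row/column labels."""
    counts = scipy.io.mmread(mtx_path)
    if sp.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"counts shape {counts.shape} does not match {len(genes)} features x {len(barcodes)} barcodes"
        )
    return counts, genes, barcodes


def read_counts_tsv(path: str):
    """Read a genes x spots TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def read_spot_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"spot metadata is missing columns: {missing}")
    return meta


def read_compositions(path: str) -> pd.DataFrame:
    comp = pd.read_csv(path, index_col=0)
    if np.any(comp.to_numpy() < -1e-12):
        raise ValueError("composition entries must be nonnegative")
    if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("composition rows must sum to 1")
    return comp


def load_st_array(
    counts_path: str,
    spots_path: str,
    features_path: Optional[str] = None,
    barcodes_path: Optional[str] = None,
    compositions_path: Optional[str] = None,
) -> STArray:
    """Assemble an :class:`STArray` from on-disk tables.

    ``counts_path`` ending in ``.mtx`` selects the Matrix Market route (the
    sidecar paths default to ``features.tsv`` / ``barcodes.tsv`` next to it);
    anything else is read as a single TSV.
    """
    if counts_path.endswith(".mtx"):
        base = os.path.dirname(counts_path)
        counts, genes, barcodes = read_counts_mtx(
            counts_path,
            features_path or os.path.join(base, "features.tsv"),
            barcodes_path or os.path.join(base, "barcodes.tsv"),
        )
    else:
        counts, genes, barcodes = read_counts_tsv(counts_path)
    meta = read_spot_metadata(spots_path).set_index("spot_id").loc[[str(b) for b in barcodes]]
    composition = celltypes = None
    if compositions_path is not None:
        comp = read_compositions(compositions_path).loc[[str(b) for b in barcodes]]
        composition = comp.to_numpy(dtype=float)
        celltypes = comp.columns.tolist()
    extra = [c for c in meta.columns if c not in {"tissue_id", "x", "y", "mroi"}]
    return STArray(
        counts=np.asarray(counts),
        gene_ids=genes,
        spot_ids=barcodes,
        coords=meta[["y", "x"]].to_numpy(dtype=int),
        tissue_id=meta["tissue_id"].to_numpy(),
        mroi=meta["mroi"].to_numpy(),
        composition=composition,
        celltypes=celltypes,
        covariates=meta[extra].reset_index(drop=True) if extra else None,
    )


def write_st_array(data: STArray, outdir: str) -> None:
    """Write an STArray back out as MTX + TSV metadata (+ composition CSV)."""
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, "counts.mtx"), sp.coo_matrix(data.counts))
    pd.Series(data.gene_ids).to_csv(os.path.join(outdir, "features.tsv"), sep="\t", index=False, header=False)
    pd.Series(data.spot_ids).to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False)
    meta = pd.DataFrame(
        {
            "spot_id": data.spot_ids,
            "tissue_id": data.tissue_id,
            "x": data.coords[:, 1],
            "y": data.coords[:, 0],
            "mroi": data.mroi,
        }
    )
    if data.covariates is not None:
        meta = pd.concat([meta, data.covariates.reset_index(drop=True)], axis=1)
    meta.to_csv(os.path.join(outdir, "spots.tsv"), sep="\t", index=False)
    if data.composition is not None:
        pd.DataFrame(data.composition, index=data.spot_ids, columns=data.celltypes).to_csv(
            os.path.join(outdir, "compositions.csv")
        )
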