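"""Spatial data model for multi-array spatial transcriptomics (ST) experiments.

An ST experiment measures the pooled transcriptome of all cells above each
barcoded capture spot on a lattice (cartesian for classic ST arrays, hexagonal
for Visium-style arrays).  This module holds the in-memory containers --
counts, integer array coordinates, per-spot annotations, compositions -- plus
the lattice bookkeeping every downstream model needs: neighbor adjacency,
tissue-section detection by lattice connectivity, count-based quality control,
and median-normalized size factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: 4-neighborhood cross pattern a retained cartesian spot must sit in
CROSS_PATTERN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

# Hex neighbor offsets, odd-row offset convention: (dy, dx) pairs depend on
# row parity.  Even rows reach up-left/up; odd rows reach up/up-right, etc.
_HEX_OFFSETS_EVEN = [(-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0)]
_HEX_OFFSETS_ODD = [(-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1)]
_CART_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


class GridType(str, Enum):
    cartesian_4 = "cartesian_4"
    hex_6 = "hex_6"


@dataclass
class STArray:
    """Gene-by-spot count data with per-spot lattice coordinates and labels.

    counts        (n_genes, n_spots) nonnegative integers
    gene_ids      length n_genes
    spot_ids      length n_spots
    coords        (n_spots, 2) integer array row/column
    tissue_id     length n_spots, tissue-section identifier per spot
    mroi          length n_spots, morphological region label per spot
    composition   optional (n_spots, n_celltypes) simplex rows
    celltypes     optional labels for the composition columns
    """

    counts: np.ndarray
    gene_ids: list
    spot_ids: list
    coords: np.ndarray
    tissue_id: np.ndarray
    mroi: np.ndarray
    composition: Optional[np.ndarray] = None
    celltypes: Optional[list] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=int)
        self.tissue_id = np.asarray(self.tissue_id)
        self.mroi = np.asarray(self.mroi)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """Per-spot UMI total (column sum of counts)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D genes x spots matrix")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be nonnegative integers")
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.spot_ids) != self.n_spots:
            raise ValueError("spot_ids length does not match counts columns")
        if self.coords.shape != (self.n_spots, 2):
            raise ValueError("coords must be (n_spots, 2)")
        for tid in np.unique(self.tissue_id):
            sub = self.coords[self.tissue_id == tid]
            if len(np.unique(sub, axis=0)) != len(sub):
                raise ValueError(f"duplicate coordinates within tissue {tid!r}")
        if self.composition is not None:
            comp = np.asarray(self.composition, dtype=float)
            if np.any(comp < -1e-12):
                raise ValueError("composition entries must be nonnegative")
            if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("composition rows must sum to 1")
            self.composition = comp

    def subset_spots(self, mask: np.ndarray) -> "STArray":
        mask = np.asarray(mask)
        return STArray(
            counts=self.counts[:, mask],
            gene_ids=list(self.gene_ids),
            spot_ids=[s for s, m in zip(self.spot_ids, mask) if m],
            coords=self.coords[mask],
            tissue_id=self.tissue_id[mask],
            mroi=self.mroi[mask],
            composition=None if self.composition is None else self.composition[mask],
            celltypes=self.celltypes,
            covariates=None if self.covariates is None else self.covariates.loc[mask].reset_index(drop=True),
        )

    def subset_genes(self, mask: np.ndarray) -> "STArray":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=self.counts[mask],
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
        )


@dataclass
class SpotGrid:
    """Neighbor structure of the spots of one tissue section.

    adjacency  symmetric 0/1 sparse matrix W with zero diagonal
    degree     per-spot neighbor counts (diagonal of K)
    grid_type  lattice convention the adjacency was built under
    """

    adjacency: sp.csr_matrix
    degree: np.ndarray
    grid_type: GridType

    def __post_init__(self):
        W = sp.csr_matrix(self.adjacency)
        if (W != W.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if W.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        deg = np.asarray(W.sum(axis=1)).ravel()
        if not np.array_equal(deg, np.asarray(self.degree)):
            raise ValueError("degree must equal adjacency row sums")
        cap = 4 if self.grid_type == GridType.cartesian_4 else 6
        if deg.max(initial=0) > cap:
            raise ValueError(f"{self.grid_type.value} spots have at most {cap} neighbors")
        self.adjacency = W
        self.degree = deg

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SizeFactors:
    """Per-spot sequencing-depth factors, median-normalized across the dataset."""

    s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if np.any(s <= 0):
            raise ValueError("size factors must be positive")
        if abs(np.median(s) - 1.0) > 1e-8:
            raise ValueError("size factors must have median 1")
        self.s = s


def _offsets_for(grid_type: GridType, row: int):
    if grid_type == GridType.cartesian_4:
        return _CART_OFFSETS
    return _HEX_OFFSETS_ODD if row % 2 else _HEX_OFFSETS_EVEN


def build_adjacency(coords: np.ndarray, grid_type: GridType | str = GridType.cartesian_4) -> SpotGrid:
    """Build the lattice adjacency W and neighbor counts K for one tissue.

    Spots at unit lattice distance are adjacent on a cartesian array; on a hex
    array each spot additionally reaches the two diagonal offsets of the
    odd-row-offset convention, for at most six neighbors.
    """
    grid_type = GridType(grid_type)
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_spots, 2) integers")
    keys = [tuple(c) for c in coords]
    index = {}
    for i, k in enumerate(keys):
        if k in index:
            raise ValueError(f"duplicate coordinates at spots {index[k]} and {i}: {k}")
        index[k] = i
    rows, cols = [], []
    for i, (y, x) in enumerate(coords):
        for dy, dx in _offsets_for(grid_type, int(y)):
            j = index.get((y + dy, x + dx))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(coords)
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W.data[:] = 1  # dedupe just in case
    return SpotGrid(adjacency=W, degree=np.asarray(W.sum(axis=1)).ravel(), grid_type=grid_type)


def split_sections(
    coords: np.ndarray,
    depth: np.ndarray,
    min_spots: int = 5,
    min_depth: int = 800,
    enforce_cross: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect tissue sections as 4-connected components and QC the spots.

    Connected components on the 4-neighborhood define candidate sections;
    sections with fewer than ``min_spots`` spots are discarded (defaults 5 for
    young-animal arrays, 10 for older ones in the study design this follows);
    spots below ``min_depth`` UMIs are then dropped; finally, spots whose
    retained neighborhood does not embed in the cross pattern
    [[0,1,0],[1,1,1],[0,1,0]] (i.e. spots left with no 4-neighbor) are
    dropped in a single pass, not iterated to a fixed point.

    Returns ``(section_labels, keep_mask)`` over the input spots; dropped
    spots carry label -1.
    """
    coords = np.asarray(coords, dtype=int)
    depth = np.asarray(depth)
    n = len(coords)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        logger.warning("split_sections called on empty input")
        return labels, np.zeros(0, dtype=bool)
    grid = build_adjacency(coords, GridType.cartesian_4)
    _, comp = connected_components(grid.adjacency, directed=False)
    sizes = np.bincount(comp)
    keep = sizes[comp] >= min_spots
    keep &= depth >= min_depth
    idx = np.flatnonzero(keep)
    if idx.size:
        if enforce_cross:
            # one pass: a surviving spot must have at least one retained
            # 4-neighbor, i.e. it matches the cross pattern somewhere
            still = np.flatnonzero(keep)
            grid2 = build_adjacency(coords[still], GridType.cartesian_4)
            lonely = grid2.degree == 0
            keep[still[lonely]] = False
        final = np.flatnonzero(keep)
        if final.size:
            grid3 = build_adjacency(coords[final], GridType.cartesian_4)
            _, comp3 = connected_components(grid3.adjacency, directed=False)
            # relabel sections densely in first-appearance order for determinism
            remap: dict[int, int] = {}
            for local, c in enumerate(comp3):
                lab = remap.setdefault(c, len(remap))
                labels[final[local]] = lab
    n_sections = labels.max() + 1 if labels.size else 0
    logger.info("split_sections: %d/%d spots retained in %d sections", int(keep.sum()), n, n_sections)
    return labels, keep


def qc_filter(
    data: STArray,
    min_gene_detect_frac: float = 0.02,
    min_spot_umi: int = 100,
) -> STArray:
    """Remove rarely detected genes, then shallow spots.

    A gene is kept when it is detected (count > 0) in at least
    ``min_gene_detect_frac`` of spots; after that, spots with fewer than
    ``min_spot_umi`` total UMIs are removed.  Defaults follow the common
    ST pipeline practice of a 2% gene-detection floor and a 100-UMI spot floor.
    """
    if not (0 <= min_gene_detect_frac <= 1):
        raise ValueError("min_gene_detect_frac must lie in [0, 1]")
    if min_spot_umi < 0:
        raise ValueError("min_spot_umi must be nonnegative")
    detect_frac = (data.counts > 0).mean(axis=1)
    gene_mask = detect_frac >= min_gene_detect_frac
    out = data.subset_genes(gene_mask)
    spot_mask = out.counts.sum(axis=0) >= min_spot_umi
    out = out.subset_spots(spot_mask)
    logger.info(
        "qc_filter: genes %d -> %d, then spots %d -> %d",
        data.n_genes, out.n_genes, data.n_spots, out.n_spots,
    )
    return out


def compute_size_factors(counts: np.ndarray) -> SizeFactors:
    """Per-spot depth divided by the dataset median depth.

    The likelihood mean is s * lambda, so rates are comparable across
    analyses regardless of sequencing depth.
    """
    depth = np.asarray(np.asarray(counts).sum(axis=0), dtype=float).ravel()
    if np.any(depth <= 0):
        bad = np.flatnonzero(depth <= 0)
        raise ValueError(f"zero-depth spots must be removed by QC first: {bad.tolist()}")
    return SizeFactors(s=depth / np.median(depth))
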