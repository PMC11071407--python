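"""Ground-truth ST data generation for validating the expression model.

Two regimes mirror how multicellular spots arise from single-cell biology:

* cluster-based -- each spot draws a composition simplex over the cell types
  of its region, then for each type draws reads from a multinomial over that
  type's normalized mean expression profile; spot counts are the pool over
  types and total exactly M reads per spot;
* cell-based -- each spot is a pool of a fixed number of individual cells
  sampled without replacement within types, their depth-normalized profiles
  summed and rounded.

A synthetic cell-typed reference with planted marker blocks (and hence known
differential-expression truth) makes the whole pipeline testable without any
external download.  Composition observability limits are emulated by pooling
types into morphological superclasses and corrupting the simplexes with
clipped Gaussian noise; local spatial correlation by blending each spot with
its lattice neighbors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .reference import ReferenceProfiles
from .spatial import STArray, SpotGrid, build_adjacency

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for simulated arrays.

    Defaults follow the validation design the model was originally assessed
    under: 12 arrays of 2,000 spots, two regions in a 1:1 ratio, 1,000 reads
    per spot (cluster-based), 10 cells per spot (cell-based).
    """

    n_arrays: int = 12
    spots_per_array: int = 2000
    regions: dict = field(default_factory=dict)  # region name -> list of member type indices
    region_ratio: Optional[np.ndarray] = None
    reads_per_spot: int = 1000
    cells_per_spot: int = 10
    noise_sd: float = 0.0
    pool_superclasses: bool = False
    smoothing: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_arrays <= 0 or self.spots_per_array <= 0 or self.reads_per_spot <= 0 or self.cells_per_spot <= 0:
            raise ValueError("all simulation sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.region_ratio is None and self.regions:
            self.region_ratio = np.full(len(self.regions), 1.0 / len(self.regions))
        if self.region_ratio is not None:
            r = np.asarray(self.region_ratio, dtype=float)
            if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-8:
                raise ValueError("region_ratio must be a simplex")
            self.region_ratio = r


@dataclass
class SimulatedST:
    data: STArray
    E_true: np.ndarray          # generating simplex per spot (n_spots, n_types)
    E_observed: np.ndarray      # pooled / corrupted simplex per spot
    de_truth: pd.DataFrame      # planted DE labels between type pairs
    celltypes: list
    uniform_fallback: np.ndarray = None  # spots zeroed-out by corruption


def synth_reference(
    n_genes: int,
    n_types: int,
    markers_per_type: int,
    seed: int = 0,
    n_cells_per_type: int = 50,
    fold_change: float = 8.0,
    dispersion: float = 2.0,
    depth: float = 2000.0,
    baseline_log_sd: float = 1.0,
    de_fold_threshold: float = 2.0,
) -> tuple[ReferenceProfiles, pd.DataFrame]:
    """Synthetic cell-typed reference with disjoint planted marker blocks.

    Gene means follow a log-normal baseline shared across types; each type
    receives ``markers_per_type`` exclusive genes whose mean is multiplied by
    ``fold_change`` in that type.  Per-cell counts are gamma-Poisson
    (negative binomial) with the given dispersion, emulating overdispersed
    snRNA-seq counts.  Returns the reference plus a planted-DE truth table
    with one row per (gene, type pair): a gene is DE for a pair when its
    planted fold ratio between the two types is >= ``de_fold_threshold``.

    The returned reference additionally carries ``planted_mean`` (genes x
    types expected counts per cell), the noise-free cluster-average profile
    the DE truth is defined from; cluster-based simulations should be driven
    by it (column-normalized) so generator and truth agree.
    """
    if markers_per_type * n_types > n_genes:
        raise ValueError("marker allocation infeasible: markers_per_type * n_types > n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t}" for t in range(n_types)]
    base = np.exp(rng.normal(0.0, baseline_log_sd, n_genes))
    mean = np.tile(base[:, None], (1, n_types))
    marker_of = np.full(n_genes, -1)
    for t in range(n_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        mean[block, t] *= fold_change
        marker_of[block] = t
    # expected counts scaled to the target depth per cell
    rate = mean / mean.sum(axis=0, keepdims=True) * depth
    counts = np.zeros((n_genes, n_types * n_cells_per_type))
    labels = np.empty(n_types * n_cells_per_type, dtype=object)
    for t in range(n_types):
        cols = slice(t * n_cells_per_type, (t + 1) * n_cells_per_type)
        lam = rng.gamma(dispersion, rate[:, t][:, None] / dispersion, (n_genes, n_cells_per_type))
        counts[:, cols] = rng.poisson(lam)
        labels[cols] = types[t]
    rows = []
    for a, b in itertools.combinations(range(n_types), 2):
        ratio = mean[:, a] / mean[:, b]
        l2fc = np.log2(ratio)
        is_de = np.maximum(ratio, 1.0 / ratio) >= de_fold_threshold
        for g in range(n_genes):
            rows.append((gene_ids[g], types[a], types[b], l2fc[g], bool(is_de[g])))
    de_truth = pd.DataFrame(rows, columns=["gene", "type_a", "type_b", "log2fc_planted", "is_de"])
    ref = ReferenceProfiles(counts=counts, gene_ids=gene_ids, cell_type=labels)
    # expected (noise-free) per-type expression; the cluster-average profile
    # the cluster-based simulator and the DE truth are both defined from
    ref.planted_mean = rate
    return ref, de_truth


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder split of ``total`` proportional to ``weights``."""
    raw = total * weights
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
    return base


def _spot_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Square-ish lattice coordinates and per-spot region assignment."""
    side = int(np.ceil(np.sqrt(cfg.spots_per_array)))
    coords = np.array([(r, c) for r in range(side) for c in range(side)][: cfg.spots_per_array])
    region_names = list(cfg.regions) if cfg.regions else ["region0"]
    ratio = cfg.region_ratio if cfg.region_ratio is not None else np.ones(1)
    # contiguous row-bands of spots per region, matching the target ratio
    n_per = _apportion(cfg.spots_per_array, ratio)
    region_of = np.repeat(np.arange(len(region_names)), n_per)
    return coords, region_names, region_of


def simulate_cluster_spots(profiles: np.ndarray, config: SimulationConfig,
                           gene_ids: Optional[list] = None,
                           celltypes: Optional[list] = None,
                           de_truth: Optional[pd.DataFrame] = None) -> SimulatedST:
    """Multinomial cluster-based simulation.

    ``profiles`` is genes x types with each column summing to 1.  Per spot a
    composition E is drawn flat-Dirichlet over the region's member types;
    reads per type are apportioned as the integer vector closest to M * E
    (largest remainder, so spot totals equal M exactly) and drawn from a
    multinomial over the type profile.
    """
    G = np.asarray(profiles, dtype=float)
    if not np.allclose(G.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("profile columns must each sum to 1")
    n_genes, n_types = G.shape
    rng = np.random.default_rng(config.seed)
    cfg = config
    if not cfg.regions:
        cfg.regions = {"region0": list(range(n_types))}
        cfg.region_ratio = np.ones(1)
    celltypes = celltypes or [f"type{t}" for t in range(n_types)]
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(n_genes)]

    counts_parts, coords_parts, tissue_parts, mroi_parts, E_parts = [], [], [], [], []
    region_names = list(cfg.regions)
    for j in range(cfg.n_arrays):
        coords, names, region_of = _spot_layout(cfg, rng)
        E = np.zeros((cfg.spots_per_array, n_types))
        y = np.zeros((n_genes, cfg.spots_per_array), dtype=int)
        for k in range(cfg.spots_per_array):
            members = np.asarray(cfg.regions[region_names[region_of[k]]], dtype=int)
            e = rng.dirichlet(np.ones(len(members)))
            E[k, members] = e
            reads = _apportion(cfg.reads_per_spot, E[k])
            for t in np.flatnonzero(reads):
                y[:, k] += rng.multinomial(reads[t], G[:, t])
        counts_parts.append(y)
        coords_parts.append(coords)
        tissue_parts.append(np.full(cfg.spots_per_array, f"array{j}", dtype=object))
        mroi_parts.append(np.array([region_names[r] for r in region_of], dtype=object))
        E_parts.append(E)
    return _assemble(cfg, counts_parts, coords_parts, tissue_parts, mroi_parts, E_parts,
                     gene_ids, celltypes, de_truth, rng)


def simulate_cell_spots(cells: ReferenceProfiles, config: SimulationConfig,
                        de_truth: Optional[pd.DataFrame] = None,
                        target_depth: float = 1000.0) -> SimulatedST:
    """Cell-based simulation: each spot pools individual reference cells.

    Cells are depth-normalized to ``target_depth`` counts; each spot's cell
    count is partitioned uniformly at random over the region's member types,
    cells are drawn without replacement within type, and their profiles are
    summed then rounded (half to even).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    types = [str(t) for t in cells.types]
    n_types = len(types)
    depth = cells.counts.sum(axis=0)
    norm = cells.counts / np.where(depth > 0, depth, 1.0) * target_depth
    cells_by_type = {t: np.flatnonzero(cells.cell_type.astype(str) == t) for t in types}
    if not cfg.regions:
        cfg.regions = {"region0": list(range(n_types))}
        cfg.region_ratio = np.ones(1)
    for name, members in cfg.regions.items():
        for t in members:
            if len(cells_by_type[types[t]]) < cfg.cells_per_spot:
                raise ValueError(
                    f"type {types[t]!r} has fewer cells than the {cfg.cells_per_spot} a spot may request"
                )
    n_genes = cells.counts.shape[0]
    region_names = list(cfg.regions)
    counts_parts, coords_parts, tissue_parts, mroi_parts, E_parts = [], [], [], [], []
    for j in range(cfg.n_arrays):
        coords, names, region_of = _spot_layout(cfg, rng)
        E = np.zeros((cfg.spots_per_array, n_types))
        y = np.zeros((n_genes, cfg.spots_per_array))
        for k in range(cfg.spots_per_array):
            members = np.asarray(cfg.regions[region_names[region_of[k]]], dtype=int)
            alloc = rng.multinomial(cfg.cells_per_spot, np.full(len(members), 1.0 / len(members)))
            E[k, members] = alloc / cfg.cells_per_spot
            for t, n_t in zip(members, alloc):
                if n_t:
                    chosen = rng.choice(cells_by_type[types[t]], size=n_t, replace=False)
                    y[:, k] += norm[:, chosen].sum(axis=1)
        counts_parts.append(np.round(y).astype(int))  # numpy rounds half to even
        coords_parts.append(coords)
        tissue_parts.append(np.full(cfg.spots_per_array, f"array{j}", dtype=object))
        mroi_parts.append(np.array([region_names[r] for r in region_of], dtype=object))
        E_parts.append(E)
    return _assemble(cfg, counts_parts, coords_parts, tissue_parts, mroi_parts, E_parts,
                     list(cells.gene_ids), types, de_truth, rng)


def _assemble(cfg, counts_parts, coords_parts, tissue_parts, mroi_parts, E_parts,
              gene_ids, celltypes, de_truth, rng) -> SimulatedST:
    counts = np.concatenate(counts_parts, axis=1)
    E_true = np.concatenate(E_parts, axis=0)
    n_spots = counts.shape[1]
    data = STArray(
        counts=counts,
        gene_ids=gene_ids,
        spot_ids=[f"s{i:06d}" for i in range(n_spots)],
        coords=np.concatenate(coords_parts, axis=0),
        tissue_id=np.concatenate(tissue_parts),
        mroi=np.concatenate(mroi_parts),
        composition=E_true.copy(),
        celltypes=list(celltypes),
    )
    if cfg.noise_sd > 0:
        # superclass pooling needs a map S and is applied via pool_and_corrupt
        E_obs, fallback = pool_and_corrupt(E_true, None, cfg.noise_sd, seed=cfg.seed + 1)
    else:
        E_obs, fallback = E_true.copy(), np.zeros(n_spots, dtype=bool)
    sim = SimulatedST(
        data=data, E_true=E_true, E_observed=E_obs,
        de_truth=de_truth if de_truth is not None else pd.DataFrame(
            columns=["gene", "type_a", "type_b", "log2fc_planted", "is_de"]),
        celltypes=list(celltypes), uniform_fallback=fallback,
    )
    if cfg.smoothing:
        sim.data = smooth_array(sim.data, cfg.smoothing)
    return sim


def pool_and_corrupt(E_true: np.ndarray, S: Optional[np.ndarray] = None,
                     noise_sd: float = 0.0, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Observed compositions: optional superclass pooling + clipped noise.

    With a (k_morph x k_sn) superclass map S the simplexes are pooled within
    superclasses; additive zero-mean Gaussian noise is then clipped
    element-wise against zero and renormalized.  Vectors that clip to zero
    fall back to the uniform simplex and are flagged.
    Returns ``(E_observed, fallback_mask)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    E = np.asarray(E_true, dtype=float)
    if S is not None:
        E = E @ np.asarray(S, dtype=float).T
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        E = E + rng.normal(0.0, noise_sd, E.shape)
    E = np.maximum(E, 0.0)
    tot = E.sum(axis=1)
    fallback = tot <= 0
    if fallback.any():
        logger.warning("%d composition vector(s) clipped to zero; set to uniform", int(fallback.sum()))
    E = np.where(fallback[:, None], 1.0 / E.shape[1], E / np.where(tot > 0, tot, 1.0)[:, None])
    return E, fallback


def smooth_array(data: STArray, weight: float) -> STArray:
    """Blend each spot's counts with its neighborhood mean, then round.

    The neighborhood of a spot includes the spot itself, so at weight 1 every
    spot becomes the (rounded) mean of its inclusive lattice neighborhood.
    """
    if not (0.0 <= weight <= 1.0):
        raise ValueError("smoothing weight must lie in [0, 1]")
    if weight == 0.0:
        return data
    new_counts = data.counts.astype(float).copy()
    for t in np.unique(data.tissue_id):
        idx = np.flatnonzero(data.tissue_id == t)
        grid = build_adjacency(data.coords[idx])
        W = grid.adjacency
        block = data.counts[:, idx].astype(float)
        hood_mean = (block + block @ W.T) / (grid.degree + 1.0)[None, :]
        new_counts[:, idx] = (1 - weight) * block + weight * hood_mean
    out = STArray(
        counts=np.round(new_counts).astype(int),
        gene_ids=list(data.gene_ids),
        spot_ids=list(data.spot_ids),
        coords=data.coords,
        tissue_id=data.tissue_id,
        mroi=data.mroi,
        composition=data.composition,
        celltypes=data.celltypes,
    )
    return out
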