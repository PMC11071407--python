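"""Hierarchical Bayesian count model for cell-type-resolved ST expression.

Each gene is modeled independently.  Counts y at spot k of tissue j follow a
Poisson / NB / ZIP / ZINB law with mean s * lambda, where s is the
median-normalized size factor and

    log lambda = B + psi + epsilon.

B is the characteristic expression rate: a one-hot MROI encoding picks the
row of a (MROI x cell type) rate matrix beta, which is dotted with the
spot's composition simplex E (compositional mode) or used directly
(non-compositional mode, one "average" cell type per MROI).  beta is
hierarchical over up to three covariate levels: the top level carries
empirical (or flat N(0, 2^2)) normal priors, deeper levels are centered on
their parents with half-normal(0,1) group scales.  psi is a conditional
autoregressive (CAR) Markov random field over each tissue's spot lattice
with precision tau * (K - alpha W), alpha ~ U(0,1), tau ~ Inv-Gamma(1,1);
epsilon is an i.i.d. spot effect with scale sigma ~ half-normal(0, 0.3).

Inference is adaptive HMC (see :mod:`stweave.hmc`): 4 chains x 250 warmup
x 250 sampling draws by default, convergence monitored by split R-hat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import hmc
from .likelihoods import Family, loglik_and_grads
from .reference import PriorMode, ReferencePriors
from .spatial import SizeFactors, SpotGrid, STArray

logger = logging.getLogger(__name__)

SPOT_EFFECT_PRIOR_SCALE = 0.3   # sigma_i ~ half-normal(0, 0.3^2)
DISPERSION_PRIOR_SCALE = 5.0    # phi ~ half-normal(0, 5^2)


@dataclass
class ModelConfig:
    family: Family = Family.poisson
    compositional: bool = True
    n_levels: int = 1
    chains: int = 4
    warmup: int = 250
    samples: int = 250
    seed: int = 0
    use_spatial: bool = True    # include the CAR field psi
    use_spot_effects: bool = True  # include epsilon
    max_leapfrog: int = 16
    target_accept: float = 0.8
    rhat_threshold: float = 1.05
    max_divergent_frac: float = 0.1

    def __post_init__(self):
        self.family = Family(self.family)
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup and samples must all be >= 1")
        if self.n_levels not in (1, 2, 3):
            raise ValueError("n_levels must be 1, 2 or 3")


@dataclass
class CovariateHierarchy:
    """Assignment of tissues to nested covariate groups (up to 3 levels).

    ``l1``/``l2``/``l3`` give one label per tissue; deeper groups are keyed
    by the full label tuple, so level-2 groups nest within level-1 groups by
    construction.  ``inverse_map(j)`` recovers the (l1, l2, l3) indices of
    tissue j.
    """

    tissues: list
    l1: Sequence
    l2: Optional[Sequence] = None
    l3: Optional[Sequence] = None

    def __post_init__(self):
        n = len(self.tissues)
        self.l1 = np.asarray(self.l1)
        if len(self.l1) != n:
            raise ValueError("l1 must assign one group per tissue")
        for name in ("l2", "l3"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != n:
                    raise ValueError(f"{name} must assign one group per tissue")
                setattr(self, name, v)
        if self.l3 is not None and self.l2 is None:
            raise ValueError("level 3 requires level 2")
        # dense group indices, keyed by the full nesting tuple
        self.g1_keys, self.g1_of_tissue = np.unique(self.l1, return_inverse=True)
        if self.l2 is not None:
            pairs = [(a, b) for a, b in zip(self.l1, self.l2)]
            self.g2_keys = sorted(set(pairs))
            k2 = {k: i for i, k in enumerate(self.g2_keys)}
            self.g2_of_tissue = np.array([k2[p] for p in pairs])
            g1k = {k: i for i, k in enumerate(self.g1_keys)}
            self.parent1_of_g2 = np.array([g1k[k[0]] for k in self.g2_keys])
        if self.l3 is not None:
            trip = [(a, b, c) for a, b, c in zip(self.l1, self.l2, self.l3)]
            self.g3_keys = sorted(set(trip))
            k3 = {k: i for i, k in enumerate(self.g3_keys)}
            self.g3_of_tissue = np.array([k3[t] for t in trip])
            k2 = {k: i for i, k in enumerate(self.g2_keys)}
            self.parent2_of_g3 = np.array([k2[k[:2]] for k in self.g3_keys])

    @property
    def depth(self) -> int:
        return 1 + (self.l2 is not None) + (self.l3 is not None)

    @property
    def n_groups(self) -> tuple[int, int, int]:
        L1 = len(self.g1_keys)
        L2 = len(self.g2_keys) if self.l2 is not None else 0
        L3 = len(self.g3_keys) if self.l3 is not None else 0
        return L1, L2, L3

    def inverse_map(self, tissue) -> tuple:
        j = self.tissues.index(tissue)
        out = [self.l1[j]]
        if self.l2 is not None:
            out.append(self.l2[j])
        if self.l3 is not None:
            out.append(self.l3[j])
        return tuple(out)

    def deepest_of_tissue(self) -> np.ndarray:
        if self.l3 is not None:
            return self.g3_of_tissue
        if self.l2 is not None:
            return self.g2_of_tissue
        return self.g1_of_tissue


def car_precision(car_alpha: float, car_tau: float, grid: SpotGrid):
    """CAR precision matrix tau * K (I - alpha K^-1 W) = tau (K - alpha W).

    Symmetric and positive definite for alpha in (0, 1) on grids without
    isolated spots.
    """
    if not (0 < car_alpha < 1):
        raise ValueError("car_alpha must lie strictly inside (0, 1)")
    if car_tau <= 0:
        raise ValueError("car_tau must be positive")
    if np.any(grid.degree == 0):
        raise ValueError("CAR precision requires no isolated spots; exclude degree-0 spots first")
    K = sp.diags(grid.degree.astype(float))
    return car_tau * (K - car_alpha * grid.adjacency)


def characteristic_rate(beta: np.ndarray, mroi_onehot: np.ndarray, composition: Optional[np.ndarray] = None) -> float:
    """B = x^T beta E (compositional) or x^T beta (non-compositional)."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    x = np.asarray(mroi_onehot, dtype=float)
    row = x @ beta
    if beta.shape[1] == 1 and composition is None:
        return float(row[0])
    if composition is None:
        if beta.shape[1] > 1:
            raise ValueError("composition required in compositional mode")
        return float(row[0])
    return float(row @ np.asarray(composition, dtype=float))


@dataclass
class ModelSpec:
    """Validated bundle of configuration, hierarchy and priors for one fit."""

    config: ModelConfig
    hierarchy: CovariateHierarchy
    priors: ReferencePriors

    def __post_init__(self):
        if self.hierarchy.depth > self.config.n_levels:
            raise ValueError(
                f"hierarchy depth {self.hierarchy.depth} exceeds configured n_levels {self.config.n_levels}"
            )
        if not self.config.compositional and self.priors.mode != PriorMode.non_compositional:
            raise ValueError("non-compositional model requires non-compositional priors")


def build_model(config: ModelConfig, hierarchy: CovariateHierarchy, priors: ReferencePriors) -> ModelSpec:
    """Assemble and validate the joint density specification."""
    return ModelSpec(config=config, hierarchy=hierarchy, priors=priors)


class _Layout:
    """Flat packing of the per-gene parameter blocks."""

    def __init__(self):
        self.blocks: dict[str, tuple[slice, tuple]] = {}
        self.dim = 0

    def add(self, name: str, shape: tuple):
        size = int(np.prod(shape)) if shape else 1
        self.blocks[name] = (slice(self.dim, self.dim + size), shape)
        self.dim += size

    def view(self, X: np.ndarray, name: str) -> np.ndarray:
        sl, shape = self.blocks[name]
        return X[:, sl].reshape(X.shape[0], *shape)

    def __contains__(self, name):
        return name in self.blocks


class GeneModel:
    """Joint log density + gradient of one gene's parameters, chain-batched."""

    def __init__(
        self,
        y: np.ndarray,
        s: np.ndarray,
        mroi_idx: np.ndarray,
        tissue_idx: np.ndarray,
        E: Optional[np.ndarray],
        spec: ModelSpec,
        grids: Optional[dict] = None,
    ):
        cfg = spec.config
        self.spec = spec
        self.y = np.asarray(y, dtype=float)
        self.s = np.asarray(s, dtype=float)
        self.n_spots = len(self.y)
        self.mroi_idx = np.asarray(mroi_idx, dtype=int)
        self.tissue_idx = np.asarray(tissue_idx, dtype=int)
        # priors.for_gene supplies the (R, C) arrays; caller sets .mu_g/.sigma_g
        self.R = len(spec.priors.mrois)
        self.C = 1
        if cfg.compositional:
            if E is None:
                raise ValueError("composition required in compositional mode")
            self.E = np.asarray(E, dtype=float)
            self.C = self.E.shape[1]
        else:
            self.E = np.ones((self.n_spots, 1))
        h = spec.hierarchy
        self.L1, self.L2, self.L3 = h.n_groups
        deepest = h.deepest_of_tissue()
        self.deep_of_spot = deepest[self.tissue_idx] if self.n_spots else np.zeros(0, dtype=int)
        self.m_idx = self.deep_of_spot * self.R + self.mroi_idx

        self.layout = _Layout()
        self.layout.add("b1", (self.L1, self.R, self.C))
        if h.depth >= 2:
            self.layout.add("b2", (self.L2, self.R, self.C))
            self.layout.add("ls2", (self.L2,))
        if h.depth >= 3:
            self.layout.add("b3", (self.L3, self.R, self.C))
            self.layout.add("ls3", (self.L3,))
        self.use_eps = cfg.use_spot_effects and self.n_spots > 0
        if self.use_eps:
            self.layout.add("eps", (self.n_spots,))
            self.layout.add("lss", ())
        self.use_psi = cfg.use_spatial and grids is not None and self.n_spots > 0
        if self.use_psi:
            self._build_car(grids)
            if self.n_car > 0:
                self.layout.add("psi", (self.n_car,))
                self.layout.add("a_raw", ())
                self.layout.add("t_raw", ())
            else:
                self.use_psi = False
        if cfg.family.overdispersed:
            self.layout.add("lphi", ())
        if cfg.family.zero_inflated:
            self.layout.add("ltheta", ())

    def _build_car(self, grids: dict):
        """Concatenate per-tissue CAR structures; degree-0 spots get psi = 0."""
        n = self.n_spots
        keep = np.zeros(n, dtype=bool)
        K_parts, W_parts, eig_parts = [], [], []
        order = []
        for t in np.unique(self.tissue_idx):
            spots_t = np.flatnonzero(self.tissue_idx == t)
            grid = grids[t]
            deg = grid.degree
            sel = deg > 0
            if (~sel).any():
                logger.info("tissue %s: %d isolated spot(s) excluded from CAR field", t, int((~sel).sum()))
            if not sel.any():
                continue
            W = grid.adjacency[np.ix_(sel, sel)]
            d = np.asarray(W.sum(axis=1)).ravel()
            # re-check: restriction can re-isolate spots
            sel2 = d > 0
            while not sel2.all():
                W = W[np.ix_(sel2, sel2)]
                idx = np.flatnonzero(sel)[sel2]
                sel = np.zeros_like(sel)
                sel[idx] = True
                d = np.asarray(W.sum(axis=1)).ravel()
                sel2 = d > 0
            if W.shape[0] == 0:
                continue
            keep[spots_t[np.flatnonzero(sel)]] = True
            order.extend(spots_t[np.flatnonzero(sel)].tolist())
            K_parts.append(d)
            W_parts.append(W)
            dhalf = 1.0 / np.sqrt(d)
            M = (W.toarray() if sp.issparse(W) else W) * np.outer(dhalf, dhalf)
            eig_parts.append(np.linalg.eigvalsh(M))
        self.n_car = len(order)
        if self.n_car:
            self.car_spots = np.asarray(order)
            self.K_diag = np.concatenate(K_parts)
            self.W_car = sp.block_diag(W_parts, format="csr")
            self.car_eigs = np.concatenate(eig_parts)
            self.log_det_K = float(np.sum(np.log(self.K_diag)))

    # -- initialization -------------------------------------------------
    def init_positions(self, rng: np.random.Generator, n_chains: int) -> np.ndarray:
        X = np.zeros((n_chains, self.layout.dim))
        mu, sig = self.mu_g, self.sigma_g
        b1 = self.layout.view(X, "b1")
        b1[:] = mu[None, None] + 0.1 * sig[None, None] * rng.standard_normal(b1.shape)
        for name in ("b2", "b3"):
            if name in self.layout:
                parent = b1.mean(axis=1, keepdims=True)
                blk = self.layout.view(X, name)
                blk[:] = parent + 0.05 * rng.standard_normal(blk.shape)
        for name, val in (("ls2", -1.0), ("ls3", -1.0), ("lss", np.log(0.1)),
                          ("t_raw", 0.0), ("lphi", np.log(5.0)), ("ltheta", -1.0)):
            if name in self.layout:
                blk = self.layout.view(X, name)
                blk[:] = val + 0.05 * rng.standard_normal(blk.shape)
        if "a_raw" in self.layout:
            blk = self.layout.view(X, "a_raw")
            blk[:] = 0.05 * rng.standard_normal(blk.shape)
        # eps / psi start at 0 (prior mode)
        return X

    # -- density --------------------------------------------------------
    def logp_grad(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.spec.config
        h = self.spec.hierarchy
        n_chains = X.shape[0]
        G = np.zeros_like(X)
        lp = np.zeros(n_chains)
        lay = self.layout

        b1 = lay.view(X, "b1")
        g_b1 = lay.view(G, "b1")
        deep_name = "b1" if h.depth == 1 else ("b2" if h.depth == 2 else "b3")
        b_deep = lay.view(X, deep_name)
        g_deep = lay.view(G, deep_name)

        # likelihood ----------------------------------------------------
        if self.n_spots:
            b_flat = b_deep.reshape(n_chains, -1, self.C)
            beta_spot = b_flat[:, self.m_idx, :]
            log_lambda = np.einsum("nkc,kc->nk", beta_spot, self.E)
            if self.use_eps:
                log_lambda = log_lambda + lay.view(X, "eps")
            if self.use_psi:
                psi = lay.view(X, "psi")
                psi_full = np.zeros((n_chains, self.n_spots))
                psi_full[:, self.car_spots] = psi
                log_lambda = log_lambda + psi_full
            phi = np.exp(lay.view(X, "lphi"))[:, None] if cfg.family.overdispersed else None
            theta = _sigmoid(lay.view(X, "ltheta"))[:, None] if cfg.family.zero_inflated else None
            ll, d_ll, d_lphi, d_ltheta = loglik_and_grads(
                self.y, self.s, log_lambda, cfg.family, phi, theta
            )
            lp += ll.sum(axis=1)
            g_flat = g_deep.reshape(n_chains, -1, self.C)
            contrib = d_ll[:, :, None] * self.E[None, :, :]
            for ch in range(n_chains):
                np.add.at(g_flat[ch], self.m_idx, contrib[ch])
            if self.use_eps:
                lay.view(G, "eps")[:] += d_ll
            if self.use_psi:
                lay.view(G, "psi")[:] += d_ll[:, self.car_spots]
            if cfg.family.overdispersed:
                lay.view(G, "lphi")[:] += d_lphi.sum(axis=1)
            if cfg.family.zero_inflated:
                lay.view(G, "ltheta")[:] += d_ltheta.sum(axis=1)

        # beta hierarchy priors -----------------------------------------
        mu, sig = self.mu_g[None, None], self.sigma_g[None, None]
        z = (b1 - mu) / sig
        lp += -0.5 * (z * z).sum(axis=(1, 2, 3))
        g_b1 += -z / sig

        if h.depth >= 2:
            b2 = lay.view(X, "b2")
            ls2 = lay.view(X, "ls2")
            s2 = np.exp(ls2)
            diff = b2 - b1[:, h.parent1_of_g2]
            inv2 = 1.0 / s2[:, :, None, None] ** 2
            sq = (diff * diff * inv2).sum(axis=(2, 3))
            lp += (-0.5 * sq - self.R * self.C * ls2).sum(axis=1)
            gd = diff * inv2
            lay.view(G, "b2")[:] += -gd
            for g2, p1 in enumerate(h.parent1_of_g2):
                g_b1[:, p1] += gd[:, g2]
            # d/dls2 of likelihood-prior term + half-normal(0,1) prior + jacobian
            lay.view(G, "ls2")[:] += sq - self.R * self.C - s2 * s2 + 1.0
            lp += (-0.5 * s2 * s2 + ls2).sum(axis=1)
        if h.depth >= 3:
            b3 = lay.view(X, "b3")
            ls3 = lay.view(X, "ls3")
            s3 = np.exp(ls3)
            b2 = lay.view(X, "b2")
            diff = b3 - b2[:, h.parent2_of_g3]
            inv3 = 1.0 / s3[:, :, None, None] ** 2
            sq = (diff * diff * inv3).sum(axis=(2, 3))
            lp += (-0.5 * sq - self.R * self.C * ls3).sum(axis=1)
            gd = diff * inv3
            lay.view(G, "b3")[:] += -gd
            for g3, p2 in enumerate(h.parent2_of_g3):
                lay.view(G, "b2")[:, p2] += gd[:, g3]
            lay.view(G, "ls3")[:] += sq - self.R * self.C - s3 * s3 + 1.0
            lp += (-0.5 * s3 * s3 + ls3).sum(axis=1)

        # spot effects ---------------------------------------------------
        if self.use_eps:
            eps = lay.view(X, "eps")
            lss = lay.view(X, "lss")
            s_sp = np.exp(lss)
            inv = 1.0 / s_sp**2
            sq = (eps * eps).sum(axis=1)
            lp += -0.5 * sq * inv - self.n_spots * lss
            lp += -0.5 * (s_sp / SPOT_EFFECT_PRIOR_SCALE) ** 2 + lss
            lay.view(G, "eps")[:] += -eps * inv[:, None]
            lay.view(G, "lss")[:] += sq * inv - self.n_spots - (s_sp / SPOT_EFFECT_PRIOR_SCALE) ** 2 + 1.0

        # CAR field ------------------------------------------------------
        if self.use_psi:
            psi = lay.view(X, "psi")
            a = _sigmoid(lay.view(X, "a_raw"))
            tau = np.exp(lay.view(X, "t_raw"))
            Wpsi = (self.W_car @ psi.T).T
            qKq = (psi * psi * self.K_diag[None, :]).sum(axis=1)
            qWq = (psi * Wpsi).sum(axis=1)
            log_det = (
                self.n_car * np.log(tau)
                + self.log_det_K
                + np.log1p(-a[:, None] * self.car_eigs[None, :]).sum(axis=1)
            )
            lp += 0.5 * log_det - 0.5 * tau * (qKq - a * qWq)
            lay.view(G, "psi")[:] += -tau[:, None] * (self.K_diag[None, :] * psi - a[:, None] * Wpsi)
            d_a = (
                -0.5 * (self.car_eigs[None, :] / (1.0 - a[:, None] * self.car_eigs[None, :])).sum(axis=1)
                + 0.5 * tau * qWq
            )
            # alpha ~ U(0,1) via logistic transform: add log-jacobian a(1-a)
            lay.view(G, "a_raw")[:] += d_a * a * (1 - a) + (1 - 2 * a)
            lp += np.log(a) + np.log1p(-a)
            d_tau = 0.5 * self.n_car / tau - 0.5 * (qKq - a * qWq)
            # tau ~ Inv-Gamma(1, 1): log p = -2 log tau - 1/tau, + jacobian t_raw
            lay.view(G, "t_raw")[:] += d_tau * tau - 1.0 + 1.0 / tau
            lp += -np.log(tau) - 1.0 / tau

        # dispersion / dropout priors -------------------------------------
        if cfg.family.overdispersed:
            lphi = lay.view(X, "lphi")
            phi = np.exp(lphi)
            lp += -0.5 * (phi / DISPERSION_PRIOR_SCALE) ** 2 + lphi
            lay.view(G, "lphi")[:] += -((phi / DISPERSION_PRIOR_SCALE) ** 2) + 1.0
        if cfg.family.zero_inflated:
            lt = lay.view(X, "ltheta")
            th = _sigmoid(lt)
            # Beta(1,2) prior ~ 2(1-theta), + logistic jacobian theta(1-theta)
            lp += np.log1p(-th) + np.log(th) + np.log1p(-th)
            lay.view(G, "ltheta")[:] += -th + (1 - 2 * th)
        return lp, G


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GenePosterior:
    """Draws for one gene, shaped (chains, draws, ...) per parameter."""

    params: dict
    rhat: dict
    converged: bool
    n_divergent: int
    layout_names: list = field(default_factory=list)
    car_spots: Optional[np.ndarray] = None  # spot indices the psi draws cover

    def beta_deep(self) -> np.ndarray:
        for name in ("b3", "b2", "b1"):
            if name in self.params:
                return self.params[name]
        raise KeyError("no beta draws present")


@dataclass
class PosteriorSamples:
    """Per-gene posteriors of a fit plus shared indexing metadata."""

    genes: list
    mrois: list
    celltypes: list
    hierarchy: CovariateHierarchy
    config: ModelConfig
    gene_posteriors: list

    def __getitem__(self, gene) -> GenePosterior:
        return self.gene_posteriors[self.genes.index(gene) if not isinstance(gene, int) else gene]

    def beta_draws(self, gene, level: str = "b1") -> np.ndarray:
        gp = self[gene]
        return gp.params[level]

    def beta_mean(self, level: str = "b1") -> np.ndarray:
        """(n_genes, groups, R, C) posterior means."""
        return np.stack([gp.params[level].mean(axis=(0, 1)) for gp in self.gene_posteriors])


def _rhat(draws: np.ndarray) -> float:
    """Split R-hat of one (chains, draws) parameter via arviz."""
    import arviz as az

    return float(az.rhat(np.asarray(draws)))


def fit(
    spec: ModelSpec,
    data: STArray,
    size_factors: SizeFactors,
    grids: Optional[dict] = None,
    gene_indices: Optional[Sequence[int]] = None,
    keep_spot_params: bool = False,
) -> PosteriorSamples:
    """Sample the posterior gene by gene with adaptive HMC.

    ``grids`` maps tissue id to a :class:`SpotGrid` and is only needed when
    the CAR field is enabled.  Genes are statistically independent, so the
    loop is trivially parallel; here it runs serially for determinism.
    """
    cfg = spec.config
    h = spec.hierarchy
    mrois = spec.priors.mrois
    mroi_to_idx = {m: i for i, m in enumerate(mrois)}
    mroi_idx = np.array([mroi_to_idx[m] for m in data.mroi])
    tissue_to_idx = {t: i for i, t in enumerate(h.tissues)}
    tissue_idx = np.array([tissue_to_idx[t] for t in data.tissue_id])
    grid_map = None
    if cfg.use_spatial and grids is not None:
        grid_map = {tissue_to_idx[t]: g for t, g in grids.items()}
    E = data.composition if cfg.compositional else None
    gene_indices = range(data.n_genes) if gene_indices is None else gene_indices

    posteriors = []
    genes = []
    for gi in gene_indices:
        genes.append(data.gene_ids[gi])
        gm = GeneModel(
            y=data.counts[gi],
            s=size_factors.s,
            mroi_idx=mroi_idx,
            tissue_idx=tissue_idx,
            E=E,
            spec=spec,
            grids=grid_map,
        )
        mu_g, sigma_g = spec.priors.for_gene(gi)
        gm.mu_g, gm.sigma_g = np.asarray(mu_g, float), np.asarray(sigma_g, float)
        rng = np.random.default_rng((cfg.seed, gi))
        x0 = gm.init_positions(rng, cfg.chains)
        res = hmc.sample(
            gm.logp_grad, x0, cfg.warmup, cfg.samples, rng,
            target_accept=cfg.target_accept, max_leapfrog=cfg.max_leapfrog,
        )
        params = {}
        for name, (sl, shape) in gm.layout.blocks.items():
            if not keep_spot_params and name in ("eps", "psi"):
                continue
            arr = res.draws[:, :, sl].reshape(cfg.chains, cfg.samples, *shape)
            params[_PARAM_NAMES.get(name, name)] = _to_natural(name, arr)
        rhats = {}
        converged = True
        for bname in ("b1", "b2", "b3"):
            if bname in gm.layout:
                sl, shape = gm.layout.blocks[bname]
                flat = res.draws[:, :, sl]
                rh = np.array([_rhat(flat[:, :, i]) for i in range(flat.shape[2])])
                rhats[bname] = rh.reshape(shape)
                if np.any(rh > cfg.rhat_threshold):
                    converged = False
        if res.n_divergent > cfg.max_divergent_frac * cfg.chains * cfg.samples:
            converged = False
        if not converged:
            logger.warning("gene %s: fit flagged non-converged", data.gene_ids[gi])
        gp = GenePosterior(
            params=params, rhat=rhats, converged=converged,
            n_divergent=res.n_divergent, layout_names=list(gm.layout.blocks),
        )
        if "psi" in gp.params:
            gp.car_spots = gm.car_spots
        posteriors.append(gp)
    return PosteriorSamples(
        genes=genes,
        mrois=list(mrois),
        celltypes=list(spec.priors.celltypes),
        hierarchy=h,
        config=cfg,
        gene_posteriors=posteriors,
    )


_PARAM_NAMES = {
    "b1": "b1", "b2": "b2", "b3": "b3",
    "ls2": "sigma_l2", "ls3": "sigma_l3",
    "eps": "epsilon", "lss": "sigma_spot",
    "psi": "psi", "a_raw": "car_alpha", "t_raw": "car_tau",
    "lphi": "dispersion", "ltheta": "dropout",
}


def _to_natural(name: str, arr: np.ndarray) -> np.ndarray:
    """Map unconstrained draws to the natural parameter scale."""
    if name in ("ls2", "ls3", "lss", "t_raw", "lphi"):
        return np.exp(arr)
    if name in ("a_raw", "ltheta"):
        return _sigmoid(arr)
    return arr


def prior_predictive(spec: ModelSpec, gene_index: int, n_draws: int, rng: np.random.Generator,
                     s: float = 1.0, composition: Optional[np.ndarray] = None) -> np.ndarray:
    """Simulate counts from the prior for one (gene, MROI=0) observation.

    Walks the hierarchy top-down (deeper levels centered on their parents
    with half-normal scales), adds the spot effect, and draws a count from
    the configured family.  Useful as a support / sanity check on the
    generative specification.
    """
    cfg = spec.config
    mu, sigma = spec.priors.for_gene(gene_index)
    C = mu.shape[1]
    if composition is None:
        composition = np.full(C, 1.0 / C)
    y = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        beta = rng.normal(mu[0], sigma[0])
        for _ in range(spec.hierarchy.depth - 1):
            scale = abs(rng.normal(0.0, 1.0))
            beta = rng.normal(beta, scale)
        log_lam = float(beta @ composition)
        if cfg.use_spot_effects:
            sig_sp = abs(rng.normal(0.0, SPOT_EFFECT_PRIOR_SCALE))
            log_lam += rng.normal(0.0, sig_sp)
        mean = s * np.exp(np.clip(log_lam, -50, 50))
        if cfg.family.overdispersed:
            phi = abs(rng.normal(0.0, DISPERSION_PRIOR_SCALE)) + 1e-6
            count = rng.negative_binomial(phi, phi / (phi + mean))
        else:
            count = rng.poisson(mean)
        if cfg.family.zero_inflated:
            theta = rng.beta(1.0, 2.0)
            if rng.uniform() < theta:
                count = 0
        y[d] = count
    return y


def predict_lambda(samples: PosteriorSamples, gene, data: STArray, size_factors: Optional[SizeFactors] = None) -> np.ndarray:
    """Per-draw, per-spot expression rates lambda = exp(B + psi + epsilon).

    Spot-level draws (psi, epsilon) are used when the fit kept them;
    otherwise lambda reduces to exp(B).
    Returns (chains, draws, n_spots).
    """
    gp = samples[gene]
    h = samples.hierarchy
    cfg = samples.config
    mroi_to_idx = {m: i for i, m in enumerate(samples.mrois)}
    mroi_idx = np.array([mroi_to_idx[m] for m in data.mroi])
    tissue_to_idx = {t: i for i, t in enumerate(h.tissues)}
    try:
        tissue_idx = np.array([tissue_to_idx[t] for t in data.tissue_id])
    except KeyError as e:
        raise ValueError(f"spot tissue {e} not part of the fitted hierarchy") from e
    deep = h.deepest_of_tissue()[tissue_idx]
    beta = gp.beta_deep()  # (chains, draws, L, R, C)
    b_spot = beta[:, :, deep, mroi_idx, :]  # (chains, draws, spots, C)
    if cfg.compositional:
        if data.composition is None:
            raise ValueError("composition required in compositional mode")
        B = np.einsum("cdkx,kx->cdk", b_spot, data.composition)
    else:
        B = b_spot[..., 0]
    log_lambda = B
    if "epsilon" in gp.params:
        if gp.params["epsilon"].shape[-1] != data.n_spots:
            raise ValueError("spot set does not match the fitted epsilon draws")
        log_lambda = log_lambda + gp.params["epsilon"]
    if "psi" in gp.params:
        psi_full = np.zeros_like(log_lambda)
        psi_full[:, :, gp.car_spots] = gp.params["psi"]
        log_lambda = log_lambda + psi_full
    return np.exp(log_lambda)
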