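"""CAR precision, characteristic rates, hierarchy, and HMC fits of the count model."""

import numpy as np
import pytest
from scipy import optimize, stats

from stweave import hmc
from stweave.model import (
    CovariateHierarchy,
    GeneModel,
    ModelConfig,
    build_model,
    car_precision,
    characteristic_rate,
    fit,
    predict_lambda,
    prior_predictive,
)
from stweave.reference import PriorMode, ReferencePriors
from stweave.spatial import STArray, SizeFactors, build_adjacency


def flat_priors(n_genes=1, R=1, C=1, compositional=False):
    shape = (n_genes, R, C)
    return ReferencePriors(
        mu=np.zeros(shape), sigma=np.full(shape, 2.0),
        gene_ids=[f"g{i}" for i in range(n_genes)],
        mrois=[f"m{i}" for i in range(R)],
        celltypes=[f"t{i}" for i in range(C)] if compositional else ["average"],
        mode=PriorMode.compositional if compositional else PriorMode.non_compositional,
    )


def line_array(y, composition=None, celltypes=None):
    y = np.atleast_2d(y)
    n = y.shape[1]
    return STArray(
        counts=y, gene_ids=[f"g{i}" for i in range(y.shape[0])],
        spot_ids=[f"s{i}" for i in range(n)],
        coords=np.array([(i, 0) for i in range(n)]),
        tissue_id=np.array(["t0"] * n), mroi=np.array(["m0"] * n),
        composition=composition, celltypes=celltypes,
    )


class TestCARPrecision:
    def test_small_alpha_approaches_diagonal(self):
        grid = build_adjacency(np.array([(0, 0), (0, 1)]))
        Q = car_precision(1e-9, 2.0, grid).toarray()
        assert np.allclose(Q, 2.0 * np.diag([1.0, 1.0]), atol=1e-8)

    def test_two_spot_closed_form(self):
        grid = build_adjacency(np.array([(0, 0), (0, 1)]))
        a = 0.7
        Q = car_precision(a, 1.0, grid).toarray()
        assert np.allclose(Q, [[1.0, -a], [-a, 1.0]])
        assert np.allclose(np.linalg.eigvalsh(Q), [1 - a, 1 + a])

    def test_invalid_parameters_rejected(self):
        grid = build_adjacency(np.array([(0, 0), (0, 1)]))
        for a, tau in [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0)]:
            with pytest.raises(ValueError):
                car_precision(a, tau, grid)

    def test_isolated_spot_rejected(self):
        grid = build_adjacency(np.array([(0, 0), (5, 5)]))
        with pytest.raises(ValueError, match="isolated"):
            car_precision(0.5, 1.0, grid)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_bruteforce(self, seed):
        """tau*K(I - a K^-1 W) built densely agrees to 1e-10 on <=50-spot grids."""
        rng = np.random.default_rng(seed)
        side = int(rng.integers(3, 8))
        coords = np.array([(r, c) for r in range(side) for c in range(side)])[:50]
        grid = build_adjacency(coords)
        keep = grid.degree > 0
        coords = coords[keep]
        grid = build_adjacency(coords)
        a, tau = float(rng.uniform(0.05, 0.95)), float(rng.uniform(0.2, 4.0))
        Q = car_precision(a, tau, grid).toarray()
        K = np.diag(grid.degree.astype(float))
        W = grid.adjacency.toarray()
        dense = tau * K @ (np.eye(len(coords)) - a * np.linalg.inv(K) @ W)
        assert np.max(np.abs(Q - dense)) < 1e-10
        assert np.all(np.linalg.eigvalsh(Q) > 0)


class TestCharacteristicRate:
    def test_pure_spot_reads_off_beta(self):
        beta = np.array([[1.5, -0.5], [0.2, 0.8]])
        B = characteristic_rate(beta, np.array([0, 1]), np.array([0.0, 1.0]))
        assert B == pytest.approx(0.8)

    def test_linearity(self):
        beta = np.array([[1.0, 3.0]])
        assert characteristic_rate(beta, np.array([1]), np.array([0.5, 0.5])) == pytest.approx(2.0)

    def test_non_compositional_ignores_composition(self):
        beta = np.array([[0.7], [1.3]])
        assert characteristic_rate(beta, np.array([0, 1])) == pytest.approx(1.3)

    def test_missing_composition_rejected(self):
        with pytest.raises(ValueError, match="composition"):
            characteristic_rate(np.ones((1, 2)), np.array([1]))


class TestHierarchy:
    def test_nesting_and_inverse_map(self):
        h = CovariateHierarchy(["A", "B", "C"], l1=["x", "x", "y"], l2=["p", "q", "p"])
        assert h.depth == 2
        assert h.n_groups == (2, 3, 0)
        assert h.inverse_map("B") == ("x", "q")

    def test_depth_exceeding_levels_rejected(self):
        h = CovariateHierarchy(["A"], l1=["x"], l2=["p"])
        with pytest.raises(ValueError, match="depth"):
            build_model(ModelConfig(n_levels=1), h, flat_priors())

    def test_single_level_model_has_no_deeper_draws(self):
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=False, chains=2,
                          warmup=20, samples=20, seed=0)
        data = line_array(np.random.default_rng(0).poisson(2, 20))
        post = fit(build_model(cfg, h, flat_priors()), data, SizeFactors(np.ones(20)))
        p = post.gene_posteriors[0].params
        assert "b1" in p and "b2" not in p and "b3" not in p


@pytest.mark.parametrize("family", ["poisson", "zip", "nb", "zinb"])
def test_prior_predictive_support(family):
    """Prior predictive counts are nonnegative integers for every family."""
    h = CovariateHierarchy(["t0"], l1=["all"])
    cfg = ModelConfig(family=family, compositional=False, n_levels=1)
    spec = build_model(cfg, h, flat_priors())
    y = prior_predictive(spec, 0, 1000, np.random.default_rng(0))
    assert y.dtype.kind == "i" and np.all(y >= 0)


class TestFit:
    def test_zero_data_gene_posterior_equals_prior(self):
        """With no observations the beta posterior reproduces its N(0,4) prior."""
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=False, chains=4, seed=0)
        spec = build_model(cfg, h, flat_priors())
        gm = GeneModel(y=np.zeros(0), s=np.ones(0), mroi_idx=np.zeros(0, dtype=int),
                       tissue_idx=np.zeros(0, dtype=int), E=None, spec=spec)
        gm.mu_g, gm.sigma_g = spec.priors.for_gene(0)
        rng = np.random.default_rng(0)
        res = hmc.sample(gm.logp_grad, gm.init_positions(rng, 4), 250, 500, rng)
        draws = res.draws.ravel()
        p = stats.kstest(draws, stats.norm(0, 2).cdf).pvalue
        assert p > 0.01

    def test_parameter_recovery_simple_poisson(self):
        """500 Poisson spots, true beta = 1, psi/eps suppressed: |mean - 1| < 0.1."""
        rng = np.random.default_rng(11)
        y = rng.poisson(np.exp(1.0), 500)
        data = line_array(y)
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=False, seed=4)
        post = fit(build_model(cfg, h, flat_priors()), data, SizeFactors(np.ones(500)))
        gp = post.gene_posteriors[0]
        assert abs(gp.params["b1"].mean() - 1.0) < 0.1
        assert gp.params["b1"].shape[:2] == (4, 250)  # chains x samples default
        assert np.all(gp.rhat["b1"] < 1.05)

    def test_posterior_mode_matches_direct_optimizer(self):
        """Single-MROI Poisson model reduces to a normal-prior log-link GLM."""
        rng = np.random.default_rng(5)
        y = rng.poisson(3.0, 100)
        s = np.ones(100)
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=False)
        spec = build_model(cfg, h, flat_priors())
        gm = GeneModel(y=y, s=s, mroi_idx=np.zeros(100, dtype=int),
                       tissue_idx=np.zeros(100, dtype=int), E=None, spec=spec)
        gm.mu_g, gm.sigma_g = spec.priors.for_gene(0)
        mode_model = optimize.minimize_scalar(
            lambda b: -gm.logp_grad(np.array([[b]]))[0][0], bounds=(-5, 5), method="bounded"
        ).x
        # independent density: Poisson log-likelihood + N(0, 2^2) prior on beta
        def direct(b):
            return -(np.sum(y * b - s * np.exp(b)) - b**2 / 8.0)
        mode_direct = optimize.minimize_scalar(direct, bounds=(-5, 5), method="bounded").x
        assert mode_model == pytest.approx(mode_direct, abs=1e-3)

    def test_draws_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(2.0, 30)
        data = line_array(y)
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=False,
                          chains=2, warmup=50, samples=50, seed=9)
        spec = build_model(cfg, h, flat_priors())
        a = fit(spec, data, SizeFactors(np.ones(30)))
        b = fit(spec, data, SizeFactors(np.ones(30)))
        assert np.array_equal(a.gene_posteriors[0].params["b1"], b.gene_posteriors[0].params["b1"])

    def test_spatial_fit_runs_and_keeps_constraints(self):
        """CAR + spot-effect fit: alpha in (0,1), tau > 0, psi defined on the lattice."""
        rng = np.random.default_rng(3)
        side = 6
        coords = np.array([(r, c) for r in range(side) for c in range(side)])
        n = len(coords)
        y = rng.poisson(3.0, n)
        data = STArray(counts=y[None], gene_ids=["g0"], spot_ids=[f"s{i}" for i in range(n)],
                       coords=coords, tissue_id=np.array(["t0"] * n), mroi=np.array(["m0"] * n))
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=True, use_spot_effects=True,
                          chains=2, warmup=100, samples=100, seed=1)
        grids = {"t0": build_adjacency(coords)}
        post = fit(build_model(cfg, h, flat_priors()), data, SizeFactors(np.ones(n)),
                   grids=grids, keep_spot_params=True)
        gp = post.gene_posteriors[0]
        assert np.all((gp.params["car_alpha"] > 0) & (gp.params["car_alpha"] < 1))
        assert np.all(gp.params["car_tau"] > 0)
        assert gp.params["psi"].shape[-1] == n
        lam = predict_lambda(post, "g0", data)
        assert lam.shape == (2, 100, n) and np.all(lam > 0)


class TestPredictLambda:
    def test_lambda_is_exp_B_without_spot_terms(self):
        rng = np.random.default_rng(8)
        E = rng.dirichlet(np.ones(2), 40)
        lam_true = E @ np.exp([1.0, 2.0])
        y = rng.poisson(lam_true)
        data = line_array(y, composition=E, celltypes=["t0", "t1"])
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=True, n_levels=1,
                          use_spatial=False, use_spot_effects=False,
                          chains=2, warmup=100, samples=100, seed=0)
        post = fit(build_model(cfg, h, flat_priors(C=2, compositional=True)),
                   data, SizeFactors(np.ones(40)))
        lam = predict_lambda(post, "g0", data)
        b = post.gene_posteriors[0].params["b1"]
        B = np.einsum("cdlrx,kx->cdk", b[:, :, :, :, :], E)
        assert np.allclose(lam, np.exp(B))

    def test_mismatched_spot_set_rejected(self):
        rng = np.random.default_rng(0)
        data = line_array(rng.poisson(2, 20))
        h = CovariateHierarchy(["t0"], l1=["all"])
        cfg = ModelConfig(family="poisson", compositional=False, n_levels=1,
                          use_spatial=False, use_spot_effects=True,
                          chains=2, warmup=50, samples=50, seed=0)
        post = fit(build_model(cfg, h, flat_priors()), data, SizeFactors(np.ones(20)),
                   keep_spot_params=True)
        other = line_array(rng.poisson(2, 10))
        with pytest.raises(ValueError, match="spot set"):
            predict_lambda(post, "g0", other)
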