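"""Sparse multi-CCA program discovery, filtering, activity and enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stweave.mcp import (
    MCPInput,
    _pmd_objective,
    _standardize,
    enrich_fisher,
    extract_mcp_genes,
    filter_programs,
    mcp_activity,
    pmd_multicca,
    select_mcp_features,
)


def make_input(mats, types=None):
    mats = [np.asarray(m, dtype=float) for m in mats]
    types = types or [f"t{i}" for i in range(len(mats))]
    genes = [[f"{t}_g{j}" for j in range(m.shape[0])] for t, m in zip(types, mats)]
    return MCPInput(beta_bar=mats, included_types=types, included_genes=genes,
                    conditions=list(range(mats[0].shape[1])))


class TestSelectFeatures:
    def test_abundant_types_all_included(self, rng):
        comp = np.full((100, 3), 1 / 3)
        bb = {f"t{i}": rng.normal(0, 1, (40, 6)) for i in range(3)}
        sel = select_mcp_features(bb, comp, [f"t{i}" for i in range(3)],
                                  [f"g{j}" for j in range(40)], list(range(6)))
        assert sel.included_types == ["t0", "t1", "t2"]

    def test_rare_type_excluded(self, rng):
        comp = np.column_stack([np.full(100, 0.951), np.full(100, 0.049)])
        bb = {"t0": rng.normal(0, 1, (40, 6)), "t1": rng.normal(0, 1, (40, 6))}
        with pytest.raises(ValueError, match="fewer than 2"):
            select_mcp_features(bb, comp, ["t0", "t1"], [f"g{j}" for j in range(40)], range(6))

    def test_top_cv_genes_selected(self, rng):
        comp = np.full((50, 2), 0.5)
        B = np.zeros((100, 5))
        B[:, :] = 1.0 + 0.001 * rng.standard_normal((100, 5))
        planted = [3, 17, 42, 66, 90]
        for g in planted:
            B[g] = rng.normal(1.0, 2.0, 5)  # high variation across conditions
        bb = {"t0": B, "t1": B.copy()}
        sel = select_mcp_features(bb, comp, ["t0", "t1"], [f"g{j}" for j in range(100)], range(5))
        assert set(sel.included_genes[0]) == {f"g{j}" for j in planted}


class TestPMD:
    def test_single_feature_perfect_correlation(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        inp = make_input([x, 2 * x])
        model = pmd_multicca(inp, penalties=[1.0, 1.0], n_programs=1)
        w1, w2 = model.variates[0]
        assert abs(w1[0]) == pytest.approx(1.0)
        assert abs(w2[0]) == pytest.approx(1.0)
        Xs = _standardize([x, 2 * x])
        assert model.objective[0] == pytest.approx((Xs[0] @ Xs[1].T).item(), rel=1e-6)

    def test_matches_exhaustive_grid_on_two_feature_toy(self, rng):
        X1 = rng.normal(0, 1, (2, 8))
        X2 = rng.normal(0, 1, (2, 8))
        c = 1.2
        inp = make_input([X1, X2])
        model = pmd_multicca(inp, penalties=[c, c], n_programs=1)
        S1, S2 = _standardize([X1, X2])
        M = S1 @ S2.T
        # exhaustive search over unit vectors at ~0.01 angular resolution
        thetas = np.arange(0, 2 * np.pi, 0.01)
        ws = np.column_stack([np.cos(thetas), np.sin(thetas)])
        feas = np.abs(ws).sum(axis=1) <= c
        ws = ws[feas]
        vals = ws @ M @ ws.T
        best = vals.max()
        assert model.objective[0] >= best - 1e-2

    def test_constraints_satisfied_and_objective_nondecreasing(self, rng):
        mats = [rng.normal(0, 1, (15, 10)) for _ in range(3)]
        inp = make_input(mats)
        cs = [1.5, 2.0, 1.8]
        model = pmd_multicca(inp, penalties=cs, n_programs=3)
        for ws in model.variates:
            for w, c in zip(ws, cs):
                assert np.linalg.norm(w) <= 1 + 1e-8
                assert np.linalg.norm(w, 1) <= c + 1e-8

    def test_infeasible_penalty_rejected(self, rng):
        inp = make_input([rng.normal(0, 1, (4, 5)), rng.normal(0, 1, (4, 5))])
        with pytest.raises(ValueError, match=">= 1"):
            pmd_multicca(inp, penalties=[0.5, 2.0])

    def test_planted_program_recovered_across_seeds(self):
        """A shared condition signal is picked up in >= 90% of its member genes."""
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            signal = rng.normal(0, 1, 12)
            mats = []
            for i in range(2):
                B = 0.3 * rng.normal(0, 1, (20, 12))
                for g in range(5):  # genes 0-4 carry the program
                    B[g] += signal * rng.uniform(0.8, 1.2)
                mats.append(B)
            inp = make_input(mats)
            # c must exceed sqrt(5) ~ 2.24 for five equal-weight members to coexist
            model = pmd_multicca(inp, penalties=[2.4, 2.4], n_programs=1, seed=seed)
            for w in model.variates[0]:
                hits += int(np.sum(np.abs(w[:5]) > 0.1))
                total += 5
        assert hits / total >= 0.9

    def test_successive_programs_orthogonal(self, rng):
        mats = [rng.normal(0, 1, (10, 12)) for _ in range(2)]
        model = pmd_multicca(make_input(mats), penalties=[2.5, 2.5], n_programs=2)
        for i in range(2):
            w_a, w_b = model.variates[0][i], model.variates[1][i]
            assert abs(w_a @ w_b) < 0.3  # deflation keeps bases near-orthogonal


class TestExtraction:
    def test_all_small_weights_give_empty_program(self, rng):
        inp = make_input([rng.normal(0, 1, (200, 6)), rng.normal(0, 1, (200, 6))])
        model = pmd_multicca(inp, penalties=[1.05, 1.05], n_programs=1)
        # overwrite with uniformly tiny weights
        model.variates[0] = [np.full(200, 0.05), np.full(200, 0.05)]
        sets = extract_mcp_genes(model)
        assert sets[0]["members"] == []

    def test_cap_at_250_genes(self, rng):
        n = 300
        inp = make_input([rng.normal(0, 1, (n, 6)), rng.normal(0, 1, (n, 6))])
        model = pmd_multicca(inp, penalties=[1.2, 1.2], n_programs=1)
        w = rng.uniform(0.2, 1.0, n)
        model.variates[0] = [w, np.zeros(n)]
        sets = extract_mcp_genes(model)
        members = sets[0]["members"]
        assert len(members) == 250
        kept_w = sorted((abs(m[3]) for m in members), reverse=True)
        assert kept_w == sorted(np.sort(np.abs(w))[-250:], reverse=True)  # top-|w| cut

    def test_sign_partition(self, rng):
        inp = make_input([rng.normal(0, 1, (4, 6)), rng.normal(0, 1, (4, 6))])
        model = pmd_multicca(inp, penalties=[1.5, 1.5], n_programs=1)
        model.variates[0] = [np.array([0.5, -0.4, 0.0, 0.2]), np.zeros(4)]
        sets = extract_mcp_genes(model)
        ups = {g for _, g, _ in sets[0]["up"]}
        downs = {g for _, g, _ in sets[0]["down"]}
        assert ups == {"t0_g0", "t0_g3"} and downs == {"t0_g1"}


class TestFiltering:
    def test_coherent_program_kept(self):
        base = np.linspace(-1, 1, 8)
        mats = [np.vstack([base * s for s in (1.0, 1.2, 0.8)]) for _ in range(2)]
        inp = make_input(mats)
        model = pmd_multicca(inp, penalties=[1.7, 1.7], n_programs=1)
        extract_mcp_genes(model)
        kept = filter_programs(model, inp)
        assert kept[0]

    def test_incoherent_program_dropped(self, rng):
        mats = [rng.normal(0, 1, (30, 10)) for _ in range(2)]
        inp = make_input(mats)
        model = pmd_multicca(inp, penalties=[3.0, 3.0], n_programs=1)
        # members whose signals are independent noise: mean self-r ~ 0
        model.variates[0] = [np.full(30, 0.3), np.full(30, 0.3)]
        extract_mcp_genes(model)
        kept = filter_programs(model, inp, min_self_corr=0.3)
        assert not kept[0]

    def test_redundant_latter_program_dropped(self):
        base = np.linspace(-1, 1, 10)
        mats = [np.vstack([base * s for s in (1.0, 1.1, 0.9, 1.05)]) for _ in range(2)]
        inp = make_input(mats)
        model = pmd_multicca(inp, penalties=[1.9, 1.9], n_programs=2)
        # both programs built from the same shared signal -> latter is redundant
        w = np.full(4, 0.5)
        model.variates = [[w, w], [w.copy(), w.copy()]]
        extract_mcp_genes(model)
        kept = filter_programs(model, inp)
        assert kept[0] and not kept[1]


class TestActivity:
    def test_zero_weights_zero_activity(self, rng):
        mats = [rng.normal(0, 1, (5, 4)), rng.normal(0, 1, (5, 4))]
        inp = make_input(mats)
        model = pmd_multicca(inp, penalties=[1.5, 1.5], n_programs=1)
        model.variates[0] = [np.zeros(5), np.zeros(5)]
        act = mcp_activity(model, inp)
        assert np.all(act == 0)

    def test_hand_arithmetic_and_linearity(self):
        B = np.array([[2.0, 4.0], [2.0, 1.0]])
        inp = make_input([B, np.zeros((2, 2))])
        model = pmd_multicca(inp, penalties=[1.4, 1.4], n_programs=1)
        model.variates[0] = [np.array([0.5, -0.5]), np.zeros(2)]
        act = mcp_activity(model, inp)
        assert act[0, 0] == pytest.approx(0.0)
        assert act[0, 1] == pytest.approx(1.5)
        doubled = make_input([2 * B, np.zeros((2, 2))])
        act2 = mcp_activity(model, doubled)
        assert np.allclose(act2, 2 * act)


class TestEnrichment:
    def test_matches_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)} | {"g15"}
        df = enrich_fisher(query, universe, {"S": gene_set})
        # one-sided Fisher p equals the hypergeometric upper tail
        p_oracle = stats.hypergeom.sf(5 - 1, 20, 10, 6)
        assert df.p[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_disjoint_query_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        df = enrich_fisher({"g9"}, universe, {"S": {f"g{i}" for i in range(5)}})
        assert df.p[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_fisher(set(), set(), {"S": {"a"}})
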