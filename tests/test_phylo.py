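"""Phylogenetic rate matrix, ancestral states, branch alignment, drift."""

import dendropy
import numpy as np
import pytest
from scipy import optimize, stats

from morphodiverge.covariance import CovMatrix
from morphodiverge.morphometrics import N_COORDS
from morphodiverge.phylo import (
    Phylogeny,
    ReconstructionOperators,
    ancestral_states,
    branch_changes,
    divergence_profile,
    drift_expectation,
    e_beta_stat,
    estimate_R,
    phylo_covariance,
    rate_alignment_test,
    read_newick,
    simulate_bm_tips,
    write_newick,
)
from morphodiverge.synthetic import SynthConfig, gen_tree, structured_cov

from conftest import random_psd


def _phy_from_newick(s):
    tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return Phylogeny(tree=tree)


def _balanced_tree(depth, blen=10.0):
    n = 2**depth
    labs = [f"t{i}" for i in range(n)]

    def nwk(lo, hi):
        if hi - lo == 1:
            return f"{labs[lo]}:{blen}"
        mid = (lo + hi) // 2
        return f"({nwk(lo, mid)},{nwk(mid, hi)}):{blen}"

    return _phy_from_newick(f"({nwk(0, n // 2)},{nwk(n // 2, n)});")


class TestTreeIO:
    def test_roundtrip_preserves_topology_and_lengths(self, tmp_path, small_phylogeny):
        p = tmp_path / "t.nwk"
        write_newick(p, small_phylogeny)
        back = read_newick(p)
        assert sorted(back.tip_labels) == sorted(small_phylogeny.tip_labels)
        assert back.depth() == pytest.approx(small_phylogeny.depth(), rel=1e-9)
        assert back.n_tips == small_phylogeny.n_tips

    def test_ultrametricity_flagged(self, tmp_path):
        (tmp_path / "bad.nwk").write_text("((a:1,b:5):1,c:9);")
        with pytest.raises(ValueError, match="ultrametric"):
            read_newick(tmp_path / "bad.nwk", require_ultrametric=True)

    def test_zero_length_branch_rejected(self, tmp_path):
        (tmp_path / "zero.nwk").write_text("((a:0,b:1):1,c:2);")
        with pytest.raises(ValueError, match="length"):
            read_newick(tmp_path / "zero.nwk")


class TestPhyloCovariance:
    def test_two_tip_definition(self):
        phy = _phy_from_newick("((a:2,b:2):3,c:5);")
        S = phylo_covariance(phy, ["a", "b", "c"])
        np.testing.assert_allclose(S, [[5, 3, 0], [3, 5, 0], [0, 0, 5]])

    def test_star_tree_diagonal(self):
        phy = _phy_from_newick("(a:4,b:4,c:4,d:4);")
        S = phylo_covariance(phy, ["a", "b", "c", "d"])
        np.testing.assert_allclose(S, 4 * np.eye(4))

    def test_positive_definite_on_random_trees(self):
        for seed in range(50):
            cfg = SynthConfig(seed=seed, n_families=8)
            phy = gen_tree(cfg)
            ev = np.linalg.eigvalsh(phylo_covariance(phy))
            assert ev.min() > 0


class TestAncestralStates:
    def test_two_tip_midpoint(self):
        phy = _phy_from_newick("(a:1,b:1);")
        tips = np.array([[0.0, 2.0], [4.0, 6.0]])
        res = ancestral_states(phy, tip_matrix=tips)
        np.testing.assert_allclose(res["root"], [2.0, 4.0], atol=1e-10)

    def test_identical_tips_constant(self, small_phylogeny):
        n = small_phylogeny.n_tips
        tips = np.tile(np.arange(3.0), (n, 1))
        res = ancestral_states(small_phylogeny, tip_matrix=tips)
        np.testing.assert_allclose(res["states"], np.tile(np.arange(3.0),
                                                          (len(res["nodes"]), 1)),
                                   atol=1e-9)

    def test_matches_independent_quadratic_minimizer(self):
        # oracle: numerically minimize sum_e |x_child - x_parent|^2 / length
        cfg = SynthConfig(seed=3, n_families=20)
        phy = gen_tree(cfg)
        ops = ReconstructionOperators(phy)
        rng = np.random.default_rng(0)
        p = 3
        tips = rng.standard_normal((phy.n_tips, p))
        res = ancestral_states(phy, tip_matrix=tips, ops=ops)

        internal = [i for i, nd in enumerate(ops.nodes) if not nd.is_leaf()]
        tip_rows = [i for i, nd in enumerate(ops.nodes) if nd.is_leaf()]
        n_int = len(internal)
        pos = {node_i: j for j, node_i in enumerate(internal)}

        def objective(flat):
            X = np.zeros((len(ops.nodes), p))
            X[tip_rows] = tips
            X[internal] = flat.reshape(n_int, p)
            return sum(np.sum((X[ci] - X[pi]) ** 2) / l for pi, ci, l in ops.edges)

        x0 = np.zeros(n_int * p)
        sol = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"gtol": 1e-14, "ftol": 1e-16,
                                         "maxiter": 20000})
        oracle = sol.x.reshape(n_int, p)
        np.testing.assert_allclose(res["states"][internal], oracle, atol=1e-6)


class TestEBeta:
    def test_matches_direct_quadratic_form(self, rng):
        C = random_psd(rng)
        Cs = C / np.trace(C)
        for _ in range(20):
            b = rng.standard_normal(N_COORDS)
            direct = (b @ Cs @ b) / (b @ b)
            assert e_beta_stat(b, Cs) == pytest.approx(direct, abs=1e-12)

    def test_leading_eigenvector_gives_top_share(self, rng):
        C = CovMatrix(random_psd(rng))
        vals, vecs = C.eigen()
        Cs = C.values / C.trace
        assert e_beta_stat(vecs[:, 0], Cs) == pytest.approx(vals[0] / C.trace,
                                                            abs=1e-12)

    def test_isotropic_matrix_constant(self, rng):
        Cs = np.eye(N_COORDS) / N_COORDS
        for _ in range(5):
            assert e_beta_stat(rng.standard_normal(N_COORDS), Cs) == \
                pytest.approx(1 / N_COORDS, abs=1e-12)

    def test_two_trait_toy(self):
        Cs = np.diag([2.0, 1.0]) / 3.0
        b = np.array([1.0, 1.0]) / np.sqrt(2)
        assert e_beta_stat(b, Cs) == pytest.approx(0.5, abs=1e-12)

    def test_scale_invariance(self, rng):
        C = random_psd(rng)
        Cs = C / np.trace(C)
        b = rng.standard_normal(N_COORDS)
        assert e_beta_stat(7.7 * b, Cs) == pytest.approx(e_beta_stat(b, Cs),
                                                         abs=1e-12)

    def test_isotropic_mean_is_one_over_dim(self, rng):
        C = random_psd(rng)
        Cs = C / np.trace(C)
        vals = [e_beta_stat(rng.standard_normal(N_COORDS), Cs)
                for _ in range(4000)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1 / N_COORDS) < 4 * se


class TestBranchChanges:
    def test_eigen_identity_and_rates(self, small_phylogeny, rng):
        C = CovMatrix(random_psd(rng), role="D", n_units=50)
        vals, vecs = C.eigen()
        ops = ReconstructionOperators(small_phylogeny)
        tips = small_phylogeny.family_means(ops.tip_labels)
        branches, n_exc = branch_changes(small_phylogeny, C, ops=ops)
        assert n_exc == 0
        for br in branches:
            assert br.rate == pytest.approx(np.linalg.norm(br.beta) / br.length_myr)
            lam_range = (vals.min() / C.trace, vals.max() / C.trace)
            assert lam_range[0] - 1e-12 <= br.e_beta <= lam_range[1] + 1e-12

    def test_zero_beta_edges_flagged(self, small_phylogeny, rng):
        C = CovMatrix(random_psd(rng), role="D")
        n = small_phylogeny.n_tips
        tips = np.zeros((n, N_COORDS))  # no evolution anywhere
        branches, n_exc = branch_changes(small_phylogeny, C, tip_matrix=tips)
        assert branches == []
        assert n_exc > 0


class TestEstimateR:
    def test_bm_recovery_and_heritability(self):
        # recovered-vs-true eigenvalue regression slope near 1 (the
        # Frobenius error itself has a ~30% sampling floor at 40 families)
        slopes, h2s = [], []
        for rep in range(10):
            cfg = SynthConfig(seed=300 + rep, n_families=40, species_per_family=10)
            phy = gen_tree(cfg)
            from morphodiverge.synthetic import gen_macro_shapes
            gen_macro_shapes(cfg, phy)
            rm = estimate_R(phy)
            ev_true = np.sort(np.linalg.eigvalsh(cfg.Sigma_true))[::-1]
            ev_hat = np.sort(np.linalg.eigvalsh(rm.R.values))[::-1]
            slopes.append(np.polyfit(ev_true[:18], ev_hat[:18], 1)[0])
            h2s.append(rm.h2_weighted)
        assert 0.8 <= np.median(slopes) <= 1.2
        assert np.median(h2s) > 0.5  # strong phylogenetic signal by design

    def test_iid_families_h2_near_zero(self):
        cfg = SynthConfig(seed=5, n_families=30, species_per_family=8)
        phy = gen_tree(cfg)
        rng = np.random.default_rng(1)
        # no phylogenetic effect: iid species scatter only
        phy.tip_data = {lab: rng.standard_normal((8, N_COORDS)) * 0.01
                        for lab in phy.tip_labels}
        rm = estimate_R(phy)
        assert rm.h2_weighted < 0.2

    def test_two_tip_closed_form_gls(self):
        # large within-family n: family means are nearly exact; R reduces to
        # the BM contrast estimate (ybar_a - ybar_b)^2 / (2T) per dimension
        phy = _phy_from_newick("(a:10,b:10);")
        rng = np.random.default_rng(2)
        delta = rng.standard_normal(N_COORDS)
        base = rng.standard_normal(N_COORDS)
        nsp = 4000
        phy.tip_data = {
            "a": base + rng.standard_normal((nsp, N_COORDS)) * 1e-3,
            "b": base + delta + rng.standard_normal((nsp, N_COORDS)) * 1e-3,
        }
        rm = estimate_R(phy, min_species=5, min_families=2)
        expected = np.outer(delta, delta) / 20.0
        np.testing.assert_allclose(np.diag(rm.R.values), np.diag(expected),
                                   rtol=0.05, atol=1e-6)

    def test_too_few_families_error(self):
        phy = _phy_from_newick("((a:1,b:1):1,c:2);")
        phy.tip_data = {t: np.zeros((6, N_COORDS)) for t in ["a", "b", "c"]}
        with pytest.raises(ValueError, match="families"):
            estimate_R(phy)


class TestRateAlignment:
    def test_deterministic_under_seed(self, small_phylogeny, small_config):
        C = CovMatrix(small_config.Sigma_dev, role="D", n_units=100)
        a = rate_alignment_test(small_phylogeny, C, n_sim=150, seed=9)
        b = rate_alignment_test(small_phylogeny, C, n_sim=150, seed=9)
        assert a["P_RAND"] == b["P_RAND"]
        np.testing.assert_array_equal(a["null_r"], b["null_r"])

    def test_orthogonal_evolution_detected(self):
        # evolution concentrated orthogonal to C's leading subspace gives a
        # correlation well below the aligned-BM null; a balanced tree with
        # equal branch lengths isolates the directional signal (on trees
        # with strongly heterogeneous edge lengths the 1/sqrt(l) component
        # of the rate dilutes the correlation for aligned and misaligned
        # evolution alike)
        cfg = SynthConfig(seed=21)
        phy = _balanced_tree(depth=5)
        C = CovMatrix(cfg.Sigma_dev, role="D", n_units=100)
        vals, vecs = C.eigen()
        # BM along the trailing eigenvectors only
        Sig_orth = (vecs[:, -8:] * vals[:8][::-1]) @ vecs[:, -8:].T
        ops = ReconstructionOperators(phy)
        rng = np.random.default_rng(3)
        tips = simulate_bm_tips(ops, Sig_orth * 1e-5, rng)
        res = rate_alignment_test(phy, C, tip_matrix=tips, n_sim=200, seed=4,
                                  ops=ops)
        assert res["P_RAND"] < 0.05

    def test_few_edges_error(self, rng):
        phy = _phy_from_newick("((a:1,b:1):1,c:2);")
        phy.tip_data = {t: rng.standard_normal((1, N_COORDS))
                        for t in ["a", "b", "c"]}
        C = CovMatrix(random_psd(rng), role="D", n_units=10)
        with pytest.raises(ValueError, match="edges"):
            rate_alignment_test(phy, C, n_sim=100, seed=0)


class TestDrift:
    def test_exact_arithmetic(self):
        out = drift_expectation(np.array([1e-6]), 1.85e8, np.array([0.037]))
        assert out["expected"].iloc[0] == pytest.approx(370.0, rel=1e-12)
        assert out["ratio"].iloc[0] == pytest.approx(1e-4, rel=1e-9)
        out2 = drift_expectation(np.array([1e-6]), 3.7e8, np.array([0.037]))
        assert out2["expected"].iloc[0] == pytest.approx(740.0, rel=1e-12)

    def test_nonpositive_vm_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            drift_expectation(np.array([0.0]), 1.0, np.array([1.0]))


class TestDivergenceProfile:
    def test_bm_slope_matches_closed_form(self):
        # E|x_a - x_b|^2 = 2 * t_div * trace(Sigma) under BM (per-species
        # pairs across families, no within-family scatter)
        cfg = SynthConfig(seed=8, n_families=30, species_per_family=3,
                          species_trace=1e-12, allometry_strength=0.0)
        phy = gen_tree(cfg)
        from morphodiverge.synthetic import gen_macro_shapes
        rates = []
        for rep in range(12):
            gen_macro_shapes(cfg, phy, seed=100 + rep)
            prof = divergence_profile(phy, n_bins=8)
            pairs = prof.attrs["pairs"]
            slope = np.polyfit(pairs["time_myr"], pairs["sq_distance"], 1)[0]
            rates.append(slope)
        expected = 2 * np.trace(cfg.Sigma_true)
        assert np.mean(rates) == pytest.approx(expected, rel=0.25)

    def test_zero_rate_flat_profile(self):
        cfg = SynthConfig(seed=9, n_families=20, species_per_family=3,
                          rate_trace=1e-30, species_trace=1e-6,
                          allometry_strength=0.0)
        phy = gen_tree(cfg)
        from morphodiverge.synthetic import gen_macro_shapes
        gen_macro_shapes(cfg, phy)
        prof = divergence_profile(phy, n_bins=5)
        # no trend: first and last bins at the same noise floor
        assert prof["mean_sq_distance"].iloc[-1] == pytest.approx(
            prof["mean_sq_distance"].iloc[0], rel=0.5)
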