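"""Procrustes machinery: TPS I/O, superimposition, ANOVA, CVA, PLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphodiverge.morphometrics import (
    N_COORDS,
    N_LANDMARKS,
    LandmarkConfig,
    TPSParseError,
    centroid_size,
    cva_loo,
    gpa,
    procrustes_anova,
    procrustes_distance,
    read_tps,
    two_block_pls,
    write_tps,
)
from morphodiverge.synthetic import consensus_shape

from conftest import aligned_table


def _random_config(rng, scale=1.0):
    return consensus_shape().reshape(N_LANDMARKS, 2) * scale + \
        rng.normal(0, 0.02, (N_LANDMARKS, 2))


def _opa_distance(a, b):
    """Independent ordinary (partial) Procrustes distance: centre, scale to
    unit centroid size, optimal rotation, residual norm."""
    def prep(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())
    A, B = prep(a), prep(b)
    U, s, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return np.linalg.norm(A @ R - B)


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

class TestTPS:
    def test_scale_applied_and_roundtrip(self, tmp_path, rng):
        coords = _random_config(rng, scale=250.0)
        lines = ["LM=11"] + [f"{x} {y}" for x, y in coords] + \
                ["SCALE=0.01", "ID=spec1"]
        path = tmp_path / "wings.tps"
        path.write_text("\n".join(lines) + "\n")
        configs, rejected = read_tps(path)
        assert not rejected
        assert len(configs) == 1
        np.testing.assert_allclose(configs[0].coords, coords * 0.01, rtol=1e-12)
        assert configs[0].specimen_id == "spec1"
        assert configs[0].has_scale

        out = tmp_path / "roundtrip.tps"
        write_tps(out, configs)
        back, _ = read_tps(out)
        np.testing.assert_allclose(back[0].coords, configs[0].coords, atol=1e-9)

    def test_wrong_landmark_count_rejected_with_report(self, tmp_path, rng):
        coords = _random_config(rng)
        good = ["LM=11"] + [f"{x} {y}" for x, y in coords]
        bad = ["LM=10"] + [f"{x} {y}" for x, y in coords[:10]]
        path = tmp_path / "mixed.tps"
        path.write_text("\n".join(bad + good) + "\n")
        configs, rejected = read_tps(path)
        assert len(configs) == 1
        assert len(rejected) == 1
        assert "LM=10" in rejected[0]

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=11\n1.0 2.0\nnot a coordinate\n")
        with pytest.raises(TPSParseError, match="line 3"):
            read_tps(path)

    def test_landmark_csv_roundtrip_bit_exact(self, tmp_path, rng):
        from morphodiverge.morphometrics import (read_landmark_csv,
                                                 write_landmark_csv)
        configs = [
            LandmarkConfig(coords=_random_config(rng), specimen_id=f"s{i}",
                           species="spA", family="famX", line="l1",
                           population="p1", side="L" if i % 2 else "R",
                           source="photo", has_scale=True, scale_factor=0.01)
            for i in range(6)
        ]
        path = tmp_path / "lm.csv"
        write_landmark_csv(path, configs)
        back = read_landmark_csv(path)
        assert len(back) == 6
        for a, b in zip(configs, back):
            np.testing.assert_array_equal(a.coords, b.coords)
            assert (a.specimen_id, a.side, a.line) == (b.specimen_id, b.side, b.line)
            assert b.scale_factor == a.scale_factor


# ---------------------------------------------------------------------------
# Centroid size and Procrustes distance
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_centroid_size_closed_form(self):
        # unit square at (+-0.5, +-0.5), repeated to 11 landmarks
        square = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_centroid_size_homogeneous_and_matches_formula(self, rng):
        coords = _random_config(rng)
        direct = np.sqrt(np.sum((coords - coords.mean(axis=0)) ** 2))
        assert centroid_size(coords) == pytest.approx(direct, abs=1e-12)
        assert centroid_size(coords * 3.7) == pytest.approx(3.7 * direct, rel=1e-12)

    def test_coincident_landmarks_error(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((11, 2)))

    def test_distance_properties(self, rng):
        a, b = rng.standard_normal((2, N_COORDS))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)
        for _ in range(100):
            x, y, z = rng.standard_normal((3, N_COORDS))
            assert procrustes_distance(x, z) <= (
                procrustes_distance(x, y) + procrustes_distance(y, z) + 1e-12)
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(a, a[:10])


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

class TestGPA:
    def test_rigid_motion_invariance(self, rng):
        base = _random_config(rng)
        theta = 1.234
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = base @ R.T * 2.5 + np.array([10.0, -3.0])
        table = gpa([LandmarkConfig(coords=base), LandmarkConfig(coords=moved)])
        assert procrustes_distance(table.shapes[0], table.shapes[1]) < 1e-9

    def test_output_invariants(self, rng):
        configs = [LandmarkConfig(coords=_random_config(rng)) for _ in range(20)]
        table = gpa(configs)
        xy = table.configs()
        np.testing.assert_allclose(xy.mean(axis=1), 0.0, atol=1e-9)
        cs = np.sqrt((xy**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(cs, 1.0, atol=1e-9)
        # the 4 Procrustes null directions carry (numerically) no variance
        ev = np.linalg.eigvalsh(np.cov(table.shapes.T))
        assert (ev > 1e-5 * ev.max()).sum() <= 18

    def test_idempotence(self, rng):
        configs = [LandmarkConfig(coords=_random_config(rng)) for _ in range(8)]
        t1 = gpa(configs)
        t2 = gpa(t1.shapes, reference=t1.consensus)
        np.testing.assert_allclose(t2.shapes, t1.shapes, atol=1e-8)

    def test_mean_pairwise_distance_matches_pairwise_opa(self, rng):
        # small isotropic noise: GPA-frame distances converge to pairwise OPA
        base = consensus_shape().reshape(N_LANDMARKS, 2)
        raws = [base + rng.normal(0, 1e-3, (N_LANDMARKS, 2)) for _ in range(50)]
        table = gpa([LandmarkConfig(coords=c) for c in raws])
        n = len(raws)
        d_gpa, d_opa = [], []
        for i in range(n):
            for j in range(i + 1, n):
                d_gpa.append(procrustes_distance(table.shapes[i], table.shapes[j]))
                d_opa.append(_opa_distance(raws[i], raws[j]))
        assert abs(np.mean(d_gpa) - np.mean(d_opa)) < 1e-6

    def test_degenerate_configuration_error(self):
        with pytest.raises(ValueError, match="coincident"):
            gpa([LandmarkConfig(coords=np.zeros((11, 2))),
                 LandmarkConfig(coords=np.ones((11, 2)))])


# ---------------------------------------------------------------------------
# Procrustes ANOVA
# ---------------------------------------------------------------------------

class TestProcrustesANOVA:
    def test_null_r2_matches_expectation_and_p_uniform(self, rng):
        # two groups from the same distribution: E[R2] ~ (g-1)/(n-1)
        n = 40
        ps, r2s = [], []
        for rep in range(60):
            shapes = rng.standard_normal((n, N_COORDS)) * 0.01
            table = aligned_table(shapes, group=["a"] * 20 + ["b"] * 20)
            res = procrustes_anova(table, "group", n_perm=199, seed=rep)
            ps.append(res["p"])
            r2s.append(res["R2"])
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), rel=0.35)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_disjoint_groups_r2_to_one(self, rng):
        a = np.tile([1.0] + [0.0] * (N_COORDS - 1), (15, 1))
        b = np.tile([0.0, 1.0] + [0.0] * (N_COORDS - 2), (15, 1))
        noise = rng.standard_normal((30, N_COORDS)) * 1e-6
        table = aligned_table(np.vstack([a, b]) + noise,
                              group=["a"] * 15 + ["b"] * 15)
        res = procrustes_anova(table, "group", n_perm=99, seed=0)
        assert res["R2"] > 0.999
        assert res["p"] == pytest.approx(1 / 100)

    def test_single_level_error(self, rng):
        table = aligned_table(rng.standard_normal((10, N_COORDS)), group="only")
        with pytest.raises(ValueError, match="single level"):
            procrustes_anova(table, "group")


# ---------------------------------------------------------------------------
# CVA with leave-one-out
# ---------------------------------------------------------------------------

class TestCVA:
    def test_separated_clusters_classified_perfectly(self, rng):
        centers = rng.standard_normal((3, N_COORDS)) * 10
        shapes = np.vstack([c + rng.standard_normal((8, N_COORDS)) * 0.01
                            for c in centers])
        table = aligned_table(shapes, group=np.repeat(list("abc"), 8))
        res = cva_loo(table, "group")
        assert res["classification_rate"] == 1.0

    def test_permuted_labels_near_chance(self, rng):
        g = 4
        shapes = rng.standard_normal((80, N_COORDS))
        labels = rng.permutation(np.repeat(list("abcd"), 20))
        table = aligned_table(shapes, group=labels)
        rate = cva_loo(table, "group")["classification_rate"]
        chance = 1 / g
        sd = np.sqrt(chance * (1 - chance) / 80)
        assert abs(rate - chance) < 3 * sd

    def test_small_groups_filtered(self, rng):
        shapes = rng.standard_normal((13, N_COORDS))
        labels = ["a"] * 6 + ["b"] * 6 + ["tiny"]
        table = aligned_table(shapes, group=labels)
        res = cva_loo(table, "group")
        assert res["n_retained"] == 12
        assert "tiny" not in res["groups_retained"]


# ---------------------------------------------------------------------------
# Two-block PLS
# ---------------------------------------------------------------------------

class TestTwoBlockPLS:
    def test_identical_blocks_r_one(self, rng):
        X = rng.standard_normal((30, 6))
        res = two_block_pls(X, X, n_perm=199, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-10)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_rotation_invariance(self, rng):
        X = rng.standard_normal((25, 8))
        Y = X @ rng.standard_normal((8, 5)) + rng.standard_normal((25, 5))
        r0 = two_block_pls(X, Y, n_perm=9, seed=1).r_pls
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        r1 = two_block_pls(X @ Q, Y, n_perm=9, seed=1).r_pls
        assert r0 == pytest.approx(r1, abs=1e-9)

    def test_type_one_error_on_independent_blocks(self, rng):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            X = rng.standard_normal((30, 5))
            Y = rng.standard_normal((30, 3))
            if two_block_pls(X, Y, n_perm=99, seed=rep).p_perm <= 0.05:
                hits += 1
        sd = np.sqrt(0.05 * 0.95 * n_rep)
        assert abs(hits - 0.05 * n_rep) <= 3 * sd

    def test_errors(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="zero-variance"):
            two_block_pls(X, np.zeros((10, 2)))
        with pytest.raises(ValueError, match="same number"):
            two_block_pls(X, rng.standard_normal((9, 2)))
        with pytest.raises(ValueError, match="n >= 4"):
            two_block_pls(X[:3], X[:3])
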