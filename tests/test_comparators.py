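import subprocess

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from dthtest import (
    DistanceMatrix,
    GroupLabels,
    betadisper_test,
    go_perm_test,
    pcoa_embed,
)
from dthtest.comparators import _anova_f, _centroid_distances, _go_statistic


class TestPCoA:
    def test_euclidean_input_reconstructs_distances(self, rng):
        pts = rng.normal(size=(10, 2))
        D = DistanceMatrix(squareform(pdist(pts)))
        emb = pcoa_embed(D)
        assert np.all(emb.eigenvalues > 0)
        recon = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(recon, D.values, atol=1e-8)

    def test_equilateral_simplex_eigenvalues(self):
        M = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        emb = pcoa_embed(DistanceMatrix(M))
        assert emb.eigenvalues.size == 2
        assert np.all(emb.eigenvalues > 0)
        assert emb.eigenvalues[0] == pytest.approx(emb.eigenvalues[1])

    def test_trace_conservation_braycurtis(self, rng):
        counts = rng.poisson(4.0, size=(9, 20)).astype(float)
        D = DistanceMatrix(squareform(pdist(counts, metric="braycurtis")))
        emb = pcoa_embed(D)
        D2 = D.values ** 2
        row = D2.mean(axis=1, keepdims=True)
        A = -0.5 * (D2 - row - row.T + D2.mean())
        assert emb.eigenvalues.sum() == pytest.approx(np.trace(A), abs=1e-10)
        assert np.any(emb.eigenvalues < 0)  # Bray-Curtis is non-Euclidean

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            pcoa_embed(DistanceMatrix([[0.0, 1.0], [1.0, 0.0]]))


class TestBetadisper:
    def test_euclidean_centroid_distance_oracle(self, rng):
        """In Euclidean geometry the embedded centroid distances must match
        distances to the group mean computed in the raw coordinate space."""
        pts = rng.normal(size=(20, 3))
        D = DistanceMatrix(squareform(pdist(pts)))
        labels = GroupLabels(["a"] * 10 + ["b"] * 10)
        emb = pcoa_embed(D)
        z = _centroid_distances(emb.positive_axes, emb.negative_axes,
                                labels.codes, 2)
        zraw = np.empty(20)
        for g in labels.groups:
            idx = labels.indices(g)
            zraw[idx] = np.linalg.norm(pts[idx] - pts[idx].mean(0), axis=1)
        np.testing.assert_allclose(z, zraw, atol=1e-8)

    def test_mirror_groups_have_near_zero_F(self, rng):
        pts1 = rng.normal(size=(9, 4))
        pts = np.vstack([pts1, pts1 + 100.0])  # identical within-group shape
        D = DistanceMatrix(squareform(pdist(pts)))
        labels = GroupLabels([1] * 9 + [2] * 9)
        res = betadisper_test(D, labels, R=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value >= 0.5

    def test_matches_vegan_on_euclidean_and_braycurtis(self, rng, tmp_path):
        """Observed F statistic agrees with R vegan::betadisper
        (type='centroid') to high precision."""
        pts = rng.normal(size=(15, 4))
        pts[8:] *= 2.0
        counts = rng.poisson(5.0, size=(15, 30)).astype(float)
        cases = [
            squareform(pdist(pts)),
            squareform(pdist(counts, metric="braycurtis")),
        ]
        for M in cases:
            labels = GroupLabels(["a"] * 8 + ["b"] * 7)
            res = betadisper_test(DistanceMatrix(M), labels, R=1, seed=0)
            fp = tmp_path / "dmat.tsv"
            np.savetxt(fp, M, delimiter="\t")
            r_code = f'''
            suppressMessages(library(vegan))
            m <- as.matrix(read.table("{fp}"))
            d <- as.dist(m)
            grp <- factor(c(rep("a",8), rep("b",7)))
            bd <- betadisper(d, grp, type="centroid")
            cat(sprintf("%.12f", anova(bd)[["F value"]][1]))
            '''
            out = subprocess.run(["Rscript", "-e", r_code],
                                 capture_output=True, text=True, check=True)
            assert res.statistic == pytest.approx(float(out.stdout), abs=1e-9)

    def test_seeded_determinism(self, euclid_toy):
        _, D, labels = euclid_toy
        r1 = betadisper_test(D, labels, R=49, seed=3)
        r2 = betadisper_test(D, labels, R=49, seed=3)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic


class TestGoPerm:
    def test_hand_computed_statistic(self):
        # Phi_1 = {2}, Phi_2 = {4}: Vhat = (2, 8), Vbar = 5, T = 2*9 + 2*9
        M = np.array([
            [0.0, 2.0, 9.0, 9.0],
            [2.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 4.0],
            [9.0, 9.0, 4.0, 0.0],
        ])
        res = go_perm_test(DistanceMatrix(M), GroupLabels([1, 1, 2, 2]),
                           R=9, seed=0)
        assert res.statistic == pytest.approx(36.0)
        assert res.group_stats == {1: 2.0, 2: 8.0}

    def test_identical_within_sets_give_zero_statistic(self, rng):
        A = squareform(pdist(rng.normal(size=(8, 3))))
        M = np.full((16, 16), 40.0)
        M[:8, :8] = A
        M[8:, 8:] = A
        np.fill_diagonal(M, 0.0)
        D = DistanceMatrix(M)
        labels = GroupLabels([1] * 8 + [2] * 8)
        res = go_perm_test(D, labels, R=49, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        # replicates tie T0 = 0 only when a permutation recreates the
        # original partition, so p sits at or just below 1
        assert res.p_value >= 0.9

    def test_scaling_cancels_in_pvalue(self, euclid_toy):
        _, D, labels = euclid_toy
        p1 = go_perm_test(D, labels, R=99, seed=5).p_value
        D3 = DistanceMatrix(3.0 * D.values, D.sample_ids)
        p3 = go_perm_test(D3, labels, R=99, seed=5).p_value
        assert p1 == p3

    def test_location_and_relabel_invariance(self, rng):
        pts = rng.normal(size=(12, 4))
        labels = GroupLabels([1] * 6 + [2] * 6)
        swapped = GroupLabels([2] * 6 + [1] * 6)
        D = DistanceMatrix(squareform(pdist(pts)))
        Dshift = DistanceMatrix(squareform(pdist(pts + 13.0)))
        t = go_perm_test(D, labels, R=9, seed=0).statistic
        assert go_perm_test(Dshift, labels, R=9, seed=0).statistic == \
            pytest.approx(t, rel=1e-10)
        assert go_perm_test(D, swapped, R=9, seed=0).statistic == \
            pytest.approx(t, rel=1e-12)

    def test_euclidean_two_point_variance_identity(self):
        # two points at distance d: U-statistic dispersion = sample variance
        x = np.array([[0.0], [3.0]])
        d = 3.0
        assert _go_statistic([np.array([d])], np.array([2.0])) == 0.0
        V = 0.5 * np.mean(np.array([d]) ** 2)
        assert V == pytest.approx(np.var(x, ddof=1))


def test_anova_f_matches_scipy(rng):
    from scipy.stats import f_oneway
    z = rng.normal(size=18)
    codes = np.array([0] * 6 + [1] * 6 + [2] * 6)
    mine = _anova_f(z, codes, 3)
    ref = f_oneway(z[:6], z[6:12], z[12:]).statistic
    assert mine == pytest.approx(ref, rel=1e-12)
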