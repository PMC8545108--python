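"""Mantel, Procrustes/PROTEST, PCoA, and envfit against independent oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from domthermo import multivariate as mv


def dist_from_points(pts):
    return pd.DataFrame(squareform(pdist(np.asarray(pts, float))))


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    return dist_from_points(pts)


class TestMantel:
    def test_self_correlation_is_one(self):
        d = random_distance(8, 0)
        assert mv.mantel(d, d, n_perm=99).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        d = random_distance(8, 1)
        assert mv.mantel(d, 2 * d, n_perm=99).r == pytest.approx(1.0)

    def test_label_mismatch_errors(self):
        d1 = random_distance(5, 2)
        d2 = random_distance(5, 3)
        d2.index = d2.columns = list("abcde")
        with pytest.raises(ValueError, match="label"):
            mv.mantel(d1, d2)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        """Exhaustive permutation p at n=5 equals a brute-force scipy oracle."""
        d1 = random_distance(5, 4)
        d2 = random_distance(5, 5)
        res = mv.mantel(d1, d2, exhaustive=True)
        m1, m2 = d1.to_numpy(), d2.to_numpy()
        tri = np.tril_indices(5, k=-1)
        r_obs = stats.pearsonr(m1[tri], m2[tri])[0]
        hits = sum(
            stats.pearsonr(m1[tri], m2[np.ix_(p, p)][tri])[0] >= r_obs - 1e-12
            for p in permutations(range(5))
        )
        assert res.n_permutations == 120
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(hits / 120, abs=1e-12)

    def test_null_r_is_small(self):
        res = mv.mantel(random_distance(20, 6), random_distance(20, 7), n_perm=99)
        assert abs(res.r) < 0.35

    def test_p_respects_add_one_bound(self):
        d = random_distance(10, 8)
        res = mv.mantel(d, d, n_perm=99, seed=1)
        assert res.p_value >= 1 / 100


class TestProcrustes:
    def test_rotated_scaled_copy_superimposes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = 3.5 * x @ rot + 2.0
        res = mv.procrustes(x, y, n_perm=49)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        a = mv.procrustes(x, y, n_perm=9).m12_squared
        b = mv.procrustes(y, x, n_perm=9).m12_squared
        assert a == pytest.approx(b, abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        res = mv.procrustes(x, y, exhaustive=True)

        def oracle_m2(a, b):
            a = a - a.mean(0); a /= np.sqrt((a**2).sum())
            b = b - b.mean(0); b /= np.sqrt((b**2).sum())
            return 1 - np.linalg.svd(a.T @ b, compute_uv=False).sum() ** 2

        obs = oracle_m2(x, y)
        hits = sum(
            oracle_m2(x, y[list(p)]) <= obs + 1e-12 for p in permutations(range(5))
        )
        assert res.m12_squared == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(hits / 120, abs=1e-12)

    def test_independent_configs_have_large_residual(self):
        rng = np.random.default_rng(3)
        res = mv.procrustes(rng.normal(size=(60, 2)), rng.normal(size=(60, 2)), n_perm=9)
        assert res.m12_squared > 0.6

    def test_in_unit_interval(self):
        rng = np.random.default_rng(4)
        res = mv.procrustes(rng.normal(size=(8, 2)), rng.normal(size=(8, 2)), n_perm=9)
        assert 0 <= res.m12_squared <= 1


class TestPcoa:
    def test_line_ordering_recovered(self):
        pts = [[0], [1], [2], [5], [9]]
        ordn = mv.pcoa(dist_from_points(pts), k=2)
        axis1 = ordn.scores.iloc[:, 0].to_numpy()
        assert (np.diff(axis1) > 0).all() or (np.diff(axis1) < 0).all()

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        d = dist_from_points(pts)
        ordn = mv.pcoa(d, k=2)
        d2 = squareform(pdist(ordn.scores.to_numpy()))
        np.testing.assert_allclose(d2, d.to_numpy(), atol=1e-9)

    def test_axes_centered(self):
        ordn = mv.pcoa(random_distance(9, 6), k=3)
        np.testing.assert_allclose(ordn.scores.mean(axis=0), 0, atol=1e-9)

    def test_k_bounds(self):
        d = random_distance(5, 7)
        with pytest.raises(ValueError):
            mv.pcoa(d, k=5)

    def test_matches_scikit_bio(self):
        """Cross-check coordinates against the independent skbio implementation."""
        skbio = pytest.importorskip("skbio")
        d = random_distance(12, 8)
        mine = mv.pcoa(d, k=2).scores.to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy())
        ).samples.to_numpy()[:, :2]
        for a in range(2):  # eigenvector sign is arbitrary
            assert np.allclose(mine[:, a], ref[:, a], atol=1e-6) or np.allclose(
                mine[:, a], -ref[:, a], atol=1e-6
            )


class TestEnvfit:
    def _ordination(self, n=10, seed=0):
        return mv.pcoa(random_distance(n, seed), k=2)

    def test_self_fit(self):
        ordn = self._ordination()
        v = ordn.scores.iloc[:, 0]
        res = mv.envfit(ordn, v.rename("ax1"), n_perm=49)[0]
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.direction[1]) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_variable(self):
        ordn = self._ordination(n=12, seed=1)
        scores = ordn.scores.to_numpy()
        rng = np.random.default_rng(2)
        v = rng.normal(size=12)
        vc = v - v.mean()
        # project out both axes -> residual is orthogonal to the ordination
        coef = np.linalg.lstsq(scores, vc, rcond=None)[0]
        resid = vc - scores @ coef
        res = mv.envfit(ordn, pd.Series(resid, index=ordn.scores.index, name="v"), n_perm=9)[0]
        assert res.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance_of_r_squared(self):
        ordn = self._ordination(n=15, seed=3)
        rng = np.random.default_rng(4)
        v = pd.Series(rng.normal(size=15), index=ordn.scores.index, name="v")
        r1 = mv.envfit(ordn, v, n_perm=9, seed=0)[0].r_squared
        r2 = mv.envfit(ordn, 100 * v + 3, n_perm=9, seed=0)[0].r_squared
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        ordn = self._ordination(n=6, seed=5)
        rng = np.random.default_rng(6)
        v = rng.normal(size=6)
        res = mv.envfit(ordn, pd.Series(v, index=ordn.scores.index, name="v"), exhaustive=True)[0]
        xc = ordn.scores.to_numpy() - ordn.scores.to_numpy().mean(0)

        def r2(vec):
            vc = vec - vec.mean()
            fitted = xc @ np.linalg.lstsq(xc, vc, rcond=None)[0]
            return (fitted @ fitted) / (vc @ vc)

        obs = r2(v)
        hits = sum(r2(v[list(p)]) >= obs - 1e-12 for p in permutations(range(6)))
        assert res.n_permutations == 720
        assert res.r_squared == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(hits / 720, abs=1e-12)

    def test_zero_variance_variable_errors(self):
        ordn = self._ordination()
        v = pd.Series(np.ones(10), index=ordn.scores.index, name="flat")
        with pytest.raises(ValueError, match="variance"):
            mv.envfit(ordn, v)
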