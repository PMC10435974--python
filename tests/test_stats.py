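import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_bc

from nemafauna import (
    bray_curtis,
    duncan_mrt,
    euclidean_distance,
    ln_transform,
    mantel_test,
    one_way_anova,
    pcoa,
)


class TestLnTransform:
    def test_values(self):
        assert ln_transform(0) == 0.0
        assert ln_transform(math.e - 1) == pytest.approx(1.0)

    def test_monotone_on_vectors(self):
        x = np.array([0.0, 1.0, 5.0, 400.0])
        y = ln_transform(x)
        assert np.all(np.diff(y) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ln_transform(-0.5)


class TestAnova:
    def test_hand_computation(self):
        res = one_way_anova({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.group_means == {"g1": 2.0, "g2": 5.0}

    def test_identical_groups(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == pytest.approx(0.0)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = one_way_anova({"a": a, "b": b})
        t, pt = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(pt)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 5) for i in range(4)}
        res = one_way_anova(groups)
        F, p = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(F)
        assert res.p == pytest.approx(p)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, np.nan, 2], "b": [3, 4, 5]})


def _lsd_decision(a, b, alpha=0.05):
    """Fisher's LSD for two groups = pooled-variance t-test."""
    _, p = sps.ttest_ind(a, b)
    return p < alpha


class TestDuncan:
    def test_all_equal_one_letter(self):
        letters = duncan_mrt({"a": [5, 5.1, 4.9], "b": [5, 5.05, 4.95], "c": [5.02, 5, 4.98]})
        assert set(letters.values()) == {"a"}

    def test_separated_group_unique_letter(self):
        groups = {
            "hi": [10.0, 10.2, 9.8],
            "m1": [5.0, 5.1, 4.9],
            "m2": [5.05, 5.0, 4.95],
            "lo": [5.02, 4.9, 5.08],
        }
        letters = duncan_mrt(groups)
        assert letters["hi"] == "a"
        assert all(letters[g] == "b" for g in ("m1", "m2", "lo"))

    def test_two_groups_coincide_with_lsd(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.normal(0, 1, 3)
            b = rng.normal(rng.uniform(0, 3), 1, 3)
            letters = duncan_mrt({"a": a, "b": b})
            duncan_sig = letters["a"] != letters["b"]
            assert duncan_sig == _lsd_decision(a, b)

    def test_containment_property(self):
        """If the extremes of a mean-ordered trio share a letter, so does the middle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            groups = {f"g{i}": rng.normal(rng.uniform(0, 2), 1, 4) for i in range(4)}
            letters = duncan_mrt(groups)
            means = {g: float(np.mean(v)) for g, v in groups.items()}
            ordered = sorted(groups, key=lambda g: -means[g])
            for i in range(4):
                for j in range(i + 2, 4):
                    shared = set(letters[ordered[i]]) & set(letters[ordered[j]])
                    for m in range(i + 1, j):
                        assert shared <= set(letters[ordered[m]])

    def test_letters_ordered_by_mean(self):
        letters = duncan_mrt(
            {"lo": [1.0, 1.1, 0.9], "hi": [9.0, 9.1, 8.9], "mid": [5.0, 5.1, 4.9]}
        )
        assert letters == {"hi": "a", "mid": "b", "lo": "c"}

    def test_unequal_sizes_harmonic_rule(self):
        letters = duncan_mrt({"a": [1, 2, 3, 2], "b": [8, 9, 10]})
        assert letters["a"] != letters["b"]


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        X = np.array([[1, 2, 0], [1, 2, 0], [0, 0, 5]])
        D = bray_curtis(X).to_numpy()
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_hand_value(self):
        D = bray_curtis(np.array([[2, 0, 1], [1, 1, 0]]))
        assert D.iloc[0, 1] == pytest.approx(0.6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2, 10, (5, 12))
        D = bray_curtis(X).to_numpy()
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(scipy_bc(X[i], X[j]), abs=1e-12)

    def test_all_zero_pair_is_nan(self):
        D = bray_curtis(np.array([[0, 0], [0, 0], [1, 2]])).to_numpy()
        assert np.isnan(D[0, 1]) and not np.isnan(D[0, 2])


def _procrustes_error(X, Y):
    """Max coordinate error after optimal rotation/reflection of Y onto X."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Yc.T @ Xc)
    return float(np.abs(Yc @ (U @ Vt) - Xc).max())


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        D = euclidean_distance(pts, standardize=False)
        res = pcoa(D)
        assert res.explained[0] == pytest.approx(1.0)
        assert res.coordinates.shape[1] == 1

    def test_two_point_closed_form(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        res = pcoa(D)
        coords = np.sort(res.coordinates.to_numpy().ravel())
        assert coords == pytest.approx([-2.0, 2.0])

    def test_recovers_2d_configuration(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(0, 2, (12, 2))
        res = pcoa(euclidean_distance(pts, standardize=False))
        assert _procrustes_error(pts, res.coordinates.to_numpy()[:, :2]) < 1e-8

    def test_matches_pca_eigenvalues(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 1, (10, 3))
        res = pcoa(euclidean_distance(pts, standardize=False))
        centred = pts - pts.mean(axis=0)
        pca_eigs = np.sort(np.linalg.eigvalsh(centred.T @ centred))[::-1]
        assert res.eigenvalues[:3] == pytest.approx(pca_eigs, abs=1e-9)

    def test_matches_skbio(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        rng = np.random.default_rng(12)
        X = rng.gamma(2, 10, (8, 20))
        D = bray_curtis(X)
        ours = pcoa(D)
        ref = skbio_pcoa(DistanceMatrix(D.to_numpy()), number_of_dimensions=0)
        n_pos = (ours.eigenvalues > 1e-10).sum()
        assert ours.eigenvalues[:n_pos] == pytest.approx(
            np.asarray(ref.eigvals)[:n_pos], abs=1e-8
        )

    def test_lingoes_removes_negative_eigenvalues(self):
        rng = np.random.default_rng(13)
        X = rng.gamma(1, 5, (7, 10))
        D = bray_curtis(X)
        plain = pcoa(D)
        fixed = pcoa(D, lingoes=True)
        assert plain.eigenvalues[-1] < -1e-10  # Bray-Curtis is semimetric
        assert fixed.eigenvalues[-1] > -1e-8

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMantel:
    def _random_distance(self, rng, n=10):
        pts = rng.normal(0, 1, (n, 3))
        return euclidean_distance(pts, standardize=False).to_numpy()

    def test_scaled_matrix_gives_r_one(self):
        rng = np.random.default_rng(0)
        D = self._random_distance(rng)
        res = mantel_test(D, 2.0 * D, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_permutation_floor(self):
        rng = np.random.default_rng(2)
        D = self._random_distance(rng, n=12)
        res = mantel_test(D, D, n_perm=999, seed=3)
        assert res.p >= 1 / 1000

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        D1, D2 = self._random_distance(rng), self._random_distance(rng)
        r1 = mantel_test(D1, D2, seed=7)
        r2 = mantel_test(D1, D2, seed=7)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        D1, D2 = self._random_distance(rng), self._random_distance(rng)
        ours = mantel_test(D1, D2, method="pearson", seed=0)
        r_ref, _, _ = skbio_distance.mantel(
            D1, D2, method="pearson", permutations=0, alternative="greater"
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-12)

    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(60):
            D1, D2 = self._random_distance(rng, 12), self._random_distance(rng, 12)
            if mantel_test(D1, D2, n_perm=199, seed=rng).p < 0.05:
                hits += 1
        assert hits / 60 <= 0.15

    def test_nonconformable_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="conformable"):
            mantel_test(self._random_distance(rng, 5), self._random_distance(rng, 6))
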