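import numpy as np
import pandas as pd
import pytest

import soilgeo as sg
from soilgeo.dataset import RasterGrid
from soilgeo.regions import holm_adjust


class TestDelineateRegions:
    def test_constant_low_raster_is_all_r2(self):
        raster = RasterGrid((0, 0), 1.0, np.full((4, 5), 2.0))
        res = sg.delineate_regions(raster)
        assert res.counts() == {"R1": 0, "R2": 20, "unassigned": 0}

    def test_between_band_gap_is_unassigned(self):
        res = sg.delineate_regions(np.array([[2.8]]))
        assert res.labels[0, 0] == ""

    def test_band_edges_inclusive(self):
        res = sg.delineate_regions(np.array([[1.9, 2.7, 2.9, 4.2]]))
        assert list(res.labels[0]) == ["R2", "R2", "R1", "R1"]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sg.delineate_regions(np.array([[2.0]]), low_band=(1.9, 3.0), high_band=(2.9, 4.2))

    def test_bimodal_synthetic_map_recovered(self, rng):
        coords = sg.regular_grid_coords(90, 10)
        model = sg.VariogramModel("spherical", 0.005, 0.02, 25.0)
        low = sg.simulate_grf(coords, model, mean=2.3, rng=rng)
        high = sg.simulate_grf(coords, model, mean=3.5, rng=rng)
        values = np.where(coords[:, 0] < 45, low, high).reshape(10, 10)
        truth = np.where(coords[:, 0] < 45, "R2", "R1").reshape(10, 10)
        res = sg.delineate_regions(values)
        in_band = res.labels != ""
        agree = (res.labels[in_band] == truth[in_band]).mean()
        assert agree >= 0.95


class TestStudentsT:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0])
        res = sg.students_t(a, a)
        assert res.t == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_permutation_invariance_of_statistic(self):
        res = sg.students_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_pooled_formula(self):
        a = np.array([4.0, 5.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        # pooled var = 1, se = sqrt(2/3), t = 3 / se
        expected_t = 3.0 / np.sqrt(2.0 / 3.0)
        res = sg.students_t(a, b)
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.df == 4

    def test_matches_scipy_pooled(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 9)
        b = rng.normal(0.5, 1.2, 9)
        res = sg.students_t(a, b)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref_t, rel=1e-10)
        assert res.p_value == pytest.approx(ref_p, rel=1e-10)

    def test_zero_spread_unequal_means(self):
        res = sg.students_t([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0
        assert res.significant

    def test_shift_invariance(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(1, 1, 9)
        r1 = sg.students_t(a, b)
        r2 = sg.students_t(a + 100.0, b + 100.0)
        assert r1.t == pytest.approx(r2.t, rel=1e-9)

    def test_holm_adjustment_is_monotone_and_conservative(self, rng):
        table = pd.DataFrame({
            "region": ["R1"] * 9 + ["R2"] * 9,
            "a": rng.normal(0, 1, 18),
            "b": np.r_[rng.normal(0, 1, 9), rng.normal(3, 1, 9)],
        })
        raw = sg.compare_groups(table)
        adj = holm_adjust(raw)
        for r, h in zip(raw, adj):
            assert h.p_value >= r.p_value - 1e-15


class TestHotelling:
    def test_identical_groups(self, rng):
        a = rng.normal(0, 1, (9, 3))
        res = sg.hotelling_t2(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_reduces_to_squared_t_for_one_variable(self, rng):
        a = rng.normal(0, 1, (9, 1))
        b = rng.normal(1, 1.5, (9, 1))
        hot = sg.hotelling_t2(a, b)
        t = sg.students_t(a[:, 0], b[:, 0])
        assert hot.t2 == pytest.approx(t.t**2, abs=1e-8)

    def test_affine_invariance(self, rng):
        a = rng.normal(0, 1, (9, 4))
        b = rng.normal(0.3, 1, (9, 4))
        base = sg.hotelling_t2(a, b)
        m = rng.normal(0, 1, (4, 4)) + 4 * np.eye(4)
        shift = rng.normal(0, 5, 4)
        trans = sg.hotelling_t2(a @ m + shift, b @ m + shift)
        assert trans.t2 == pytest.approx(base.t2, abs=1e-8)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(0, 1, (9, 3))
        b = rng.normal(0.5, 1, (9, 3))
        res = sg.hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a, b)
        assert res.t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-8)
        assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_too_many_variables_rejected(self, rng):
        a = rng.normal(0, 1, (5, 10))
        b = rng.normal(0, 1, (5, 10))
        with pytest.raises(ValueError, match="too few samples"):
            sg.hotelling_t2(a, b)


def brute_force_ward_heights(x):
    """Greedy Ward merges via the within-cluster sum-of-squares objective.

    Independent of scipy's Lance-Williams recurrence: the merge cost is
    computed from cluster centroids, Delta ESS = n_i n_j / (n_i + n_j) *
    ||c_i - c_j||^2, reported on the distance scale sqrt(2 * Delta ESS).
    """
    clusters = [[i] for i in range(len(x))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ci = x[clusters[i]].mean(axis=0)
                cj = x[clusters[j]].mean(axis=0)
                ni, nj = len(clusters[i]), len(clusters[j])
                cost = ni * nj / (ni + nj) * np.sum((ci - cj) ** 2)
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        heights.append(np.sqrt(2 * cost))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestWardCluster:
    def test_two_points_merge_at_euclidean_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        res = sg.ward_cluster(x, n_groups=1)
        assert res.linkage[0, 2] == pytest.approx(5.0)

    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(0, 0.2, (10, 3))
        b = rng.normal(8, 0.2, (10, 3))
        res = sg.ward_cluster(np.vstack([a, b]), n_groups=2)
        labels = res.labels
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_merge_heights_match_brute_force(self, rng, n):
        x = rng.normal(0, 1, (n, 3))
        res = sg.ward_cluster(x, n_groups=1)
        np.testing.assert_allclose(
            np.sort(res.linkage[:, 2]), np.sort(brute_force_ward_heights(x)), rtol=1e-9
        )

    def test_heights_nondecreasing(self, rng):
        x = rng.normal(0, 1, (15, 4))
        res = sg.ward_cluster(x, n_groups=2)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_too_many_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            sg.ward_cluster(rng.normal(0, 1, (3, 2)), n_groups=4)


class TestPca:
    def test_perfectly_correlated_pair(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        res = sg.pca(x)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-12)
        assert res.explained_percent[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_equals_p(self, rng):
        x = rng.normal(0, 1, (20, 5))
        res = sg.pca(x)
        assert res.eigenvalues.sum() == pytest.approx(5.0, rel=1e-10)
        assert res.explained_percent.sum() == pytest.approx(100.0)

    def test_loadings_match_svd_oracle(self, rng):
        x = rng.normal(0, 1, (20, 5))
        res = sg.pca(x)
        xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        eig = s**2 / (len(x) - 1)
        load = vt.T * np.sqrt(eig)
        for j in range(5):  # align sign convention
            k = np.argmax(np.abs(load[:, j]))
            if load[k, j] < 0:
                load[:, j] = -load[:, j]
        np.testing.assert_allclose(res.loadings.to_numpy(), load, atol=1e-8)

    def test_loadings_reconstruct_correlation_matrix(self, rng):
        x = rng.normal(0, 1, (30, 4))
        res = sg.pca(x)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L @ L.T, np.corrcoef(x, rowvar=False), atol=1e-8)

    def test_explained_variance_nonincreasing(self, rng):
        x = rng.normal(0, 1, (25, 6))
        res = sg.pca(x)
        assert np.all(np.diff(res.explained_percent) <= 1e-12)

    def test_kaiser_retention_and_interpretation(self, rng):
        shared = rng.normal(0, 1, 30)
        x = np.column_stack([
            shared + rng.normal(0, 0.3, 30),
            shared + rng.normal(0, 0.3, 30),
            rng.normal(0, 1, 30),
        ])
        res = sg.pca(x)
        assert "PC1" in res.retained
        assert all(res.eigenvalues[int(c[2:]) - 1] > 1 for c in res.retained)
        assert {"var1", "var2"} <= set(res.interpreted["PC1"])

    def test_constant_column_rejected(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            sg.pca(x)
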