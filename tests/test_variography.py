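import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import soilgeo as sg
from soilgeo.variography import FitDiagnostics, SDI_MODEL_FACTORS

from conftest import brute_force_variogram


class TestModelSemivariance:
    def test_zero_at_origin(self):
        m = sg.VariogramModel("spherical", 0.2, 1.0, 10.0)
        assert sg.model_semivariance(m, 0.0) == 0.0

    def test_spherical_reaches_sill_at_range(self):
        m = sg.VariogramModel("spherical", 0.2, 1.0, 10.0)
        assert sg.model_semivariance(m, 10.0) == pytest.approx(1.2, abs=1e-15)
        assert sg.model_semivariance(m, 50.0) == pytest.approx(1.2, abs=1e-15)

    def test_spherical_hand_value_inside_range(self):
        # 0.2 + 1.0 * (1.5*0.5 - 0.5*0.125) = 0.8875
        m = sg.VariogramModel("spherical", 0.2, 1.0, 10.0)
        assert sg.model_semivariance(m, 5.0) == pytest.approx(0.8875, abs=1e-12)

    def test_practical_range_is_exactly_95_percent(self):
        e = sg.VariogramModel("exponential", 0.0, 1.0, 30.0)
        g = sg.VariogramModel("gaussian", 0.0, 1.0, 30.0)
        assert sg.model_semivariance(e, 30.0) == pytest.approx(0.95, abs=1e-12)
        assert sg.model_semivariance(g, 30.0) == pytest.approx(0.95, abs=1e-12)

    def test_negative_h_rejected(self):
        m = sg.VariogramModel("spherical", 0.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            sg.model_semivariance(m, -1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kind=st.sampled_from(["spherical", "exponential", "gaussian"]),
        c0=st.floats(0, 10),
        c1=st.floats(0, 10),
        a=st.floats(0.5, 100),
    )
    def test_nondecreasing_in_h(self, kind, c0, c1, a):
        m = sg.VariogramModel(kind, c0, c1, a)
        h = np.linspace(0, 3 * a, 200)
        g = sg.model_semivariance(m, h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sg.VariogramModel("spherical", -0.1, 1.0, 10.0)
        with pytest.raises(ValueError):
            sg.VariogramModel("spherical", 0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            sg.VariogramModel("cubic", 0.1, 1.0, 10.0)


class TestEmpiricalVariogram:
    def test_constant_attribute_gives_zero_semivariance(self, rng):
        coords = rng.uniform(0, 40, size=(12, 2))
        ds = sg.PointDataset(
            pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": np.full(12, 3.5)})
        )
        emp = sg.empirical_variogram(ds, "z")
        assert np.all(emp.semivariances == 0.0)

    def test_two_point_hand_case(self):
        ds = sg.PointDataset(pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0], "z": [1.0, 3.0]}))
        emp = sg.empirical_variogram(ds, "z", bin_width=10.0, max_lag=20.0)
        assert emp.n_bins == 1
        assert emp.pair_counts[0] == 1
        assert emp.semivariances[0] == pytest.approx(2.0)  # (3-1)^2 / (2*1)

    def test_matches_brute_force_enumeration(self, small_dataset):
        emp = sg.empirical_variogram(small_dataset, "z", bin_width=5.0, max_lag=40.0)
        lags, gammas, npairs = brute_force_variogram(
            small_dataset.coords, small_dataset.values("z"), 5.0, 40.0
        )
        np.testing.assert_allclose(emp.lags, lags, rtol=1e-12)
        np.testing.assert_allclose(emp.semivariances, gammas, rtol=1e-12)
        np.testing.assert_array_equal(emp.pair_counts, npairs)

    def test_pair_count_bookkeeping(self, small_dataset):
        max_lag = 30.0
        emp = sg.empirical_variogram(small_dataset, "z", bin_width=5.0, max_lag=max_lag)
        from scipy.spatial.distance import pdist

        expected = int(np.sum(pdist(small_dataset.coords) < max_lag))
        assert int(emp.pair_counts.sum()) == expected

    def test_nan_values_raise(self):
        ds = sg.PointDataset(
            pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0], "z": [1.0, np.nan, 2.0]})
        )
        with pytest.raises(ValueError, match="non-finite"):
            sg.empirical_variogram(ds, "z")

    def test_unknown_attribute_raises(self, small_dataset):
        with pytest.raises(KeyError):
            sg.empirical_variogram(small_dataset, "missing")

    def test_no_pairs_within_max_lag_raises(self):
        ds = sg.PointDataset(pd.DataFrame({"x": [0.0, 50.0], "y": [0.0, 0.0], "z": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="max_lag"):
            sg.empirical_variogram(ds, "z", bin_width=1.0, max_lag=5.0)


class TestFitVariogram:
    def test_noiseless_self_consistency(self):
        truth = sg.VariogramModel("spherical", 0.15, 0.10, 27.0)
        lags = np.arange(5.0, 65.0, 5.0)
        emp = sg.EmpiricalVariogram(
            lags=lags,
            semivariances=sg.model_semivariance(truth, lags),
            pair_counts=np.full(len(lags), 50),
            bin_width=5.0,
            max_lag=65.0,
        )
        model, diag = sg.fit_variogram(emp, "spherical")
        assert model.nugget == pytest.approx(0.15, abs=1e-6)
        assert model.partial_sill == pytest.approx(0.10, abs=1e-6)
        assert model.range_ == pytest.approx(27.0, abs=1e-4)
        assert diag.r2 == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_yields_mostly_nugget(self, rng):
        coords = sg.regular_grid_coords(90, 10)
        ratios = []
        for _ in range(50):
            z = rng.normal(0, 1, len(coords))
            ds = sg.PointDataset(
                pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": z}), 10.0
            )
            emp = sg.empirical_variogram(ds, "z")
            model, _ = sg.fit_variogram(emp, "spherical", sample_variance=float(np.var(z, ddof=1)))
            ratios.append(model.partial_sill / model.sill)
        assert np.median(ratios) < 0.1

    def test_too_few_bins_raises(self):
        emp = sg.EmpiricalVariogram(
            lags=np.array([5.0, 10.0, 15.0]),
            semivariances=np.array([1.0, 1.1, 1.2]),
            pair_counts=np.array([5, 5, 5]),
            bin_width=5.0,
            max_lag=20.0,
        )
        with pytest.raises(ValueError, match="bins"):
            sg.fit_variogram(emp, "spherical")


class TestSelectModel:
    def _cand(self, ssr, r2, rmse=None):
        return (sg.VariogramModel("spherical", 0.1, 1.0, 10.0), FitDiagnostics(ssr, r2, rmse))

    def test_single_candidate_is_chosen(self):
        c = self._cand(1.0, 0.9)
        assert sg.select_model([c])[0] is c

    def test_lower_ssr_wins(self):
        lo, hi = self._cand(1.0, 0.9), self._cand(2.0, 0.9)
        assert sg.select_model([hi, lo])[0] is lo

    def test_ssr_tie_broken_by_r2_then_rmse(self):
        a, b = self._cand(1.0, 0.95), self._cand(1.0, 0.90)
        assert sg.select_model([b, a])[0] is a
        c, d = self._cand(1.0, 0.95, rmse=0.5), self._cand(1.0, 0.95, rmse=0.4)
        assert sg.select_model([c, d])[0] is d

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            sg.select_model([])


class TestSpatialDependenceIndex:
    MD = 127.28

    def test_reference_fco2_row_is_weak(self):
        m = sg.VariogramModel("spherical", 0.156, 0.257 - 0.156, 26.74)
        res = sg.spatial_dependence_index(m, self.MD)
        assert res.sdi_percent == pytest.approx(6.2, abs=0.1)
        assert res.dependence_class == "weak"

    def test_reference_sand_row_is_strong(self):
        m = sg.VariogramModel("spherical", 0.378, 2.46 - 0.378, 53.98)
        res = sg.spatial_dependence_index(m, self.MD)
        assert res.sdi_percent == pytest.approx(26.9, abs=0.1)
        assert res.dependence_class == "strong"

    def test_pure_nugget_is_weak_zero(self):
        m = sg.VariogramModel("spherical", 1.0, 0.0, 10.0)
        res = sg.spatial_dependence_index(m, self.MD)
        assert res.sdi_percent == 0.0
        assert res.dependence_class == "weak"

    def test_zero_sill_degenerate_case(self):
        m = sg.VariogramModel("exponential", 0.0, 0.0, 10.0)
        res = sg.spatial_dependence_index(m, self.MD)
        assert res.sdi_percent == 0.0
        assert res.dependence_class == "weak"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(1e-3, 1e6),
        c0=st.floats(0.01, 5.0),
        c1=st.floats(0.01, 5.0),
        a=st.floats(1.0, 120.0),
    )
    def test_invariant_to_unit_rescaling(self, scale, c0, c1, a):
        m1 = sg.VariogramModel("spherical", c0, c1, a)
        m2 = sg.VariogramModel("spherical", c0 * scale, c1 * scale, a)
        r1 = sg.spatial_dependence_index(m1, self.MD)
        r2 = sg.spatial_dependence_index(m2, self.MD)
        assert r1.sdi_percent == pytest.approx(r2.sdi_percent, rel=1e-9)

    def test_range_capped_at_half_max_distance(self):
        near = sg.VariogramModel("spherical", 0.0, 1.0, self.MD / 2)
        far = sg.VariogramModel("spherical", 0.0, 1.0, self.MD)
        r_near = sg.spatial_dependence_index(near, self.MD)
        r_far = sg.spatial_dependence_index(far, self.MD)
        assert r_near.sdi_percent == pytest.approx(r_far.sdi_percent)
        assert r_far.sdi_percent == pytest.approx(SDI_MODEL_FACTORS["spherical"] * 100)
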