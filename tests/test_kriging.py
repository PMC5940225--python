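"""Semivariogram estimation, variogram fitting and ordinary kriging."""

import numpy as np
import pandas as pd
import pytest

from reefbudget import kriging, synth
from reefbudget.kriging import (SpatialSample, VariogramModel,
                                empirical_semivariogram, fit_variogram,
                                fit_variogram_ml, make_grid, ordinary_krige,
                                project_lonlat)


class TestProjection:
    def test_meridional_degree_near_palau(self):
        # 0.01 deg of latitude at 7.5 N is ~1105.8 m of meridional arc
        xy = project_lonlat([134.5, 134.5], [7.5, 7.51], ref=(134.5, 7.5))
        north = xy[1, 1] - xy[0, 1]
        assert north == pytest.approx(1105.8, rel=1e-3)

    def test_zonal_degree_scales_with_cos_latitude(self):
        xy = project_lonlat([134.5, 134.51], [7.5, 7.5], ref=(134.5, 7.5))
        east = xy[1, 0] - xy[0, 0]
        assert east == pytest.approx(1113.2 * np.cos(np.radians(7.5)), rel=1e-3)

    def test_degrees_never_used_as_meters(self):
        # a degree box must project to ~1e5 m, not ~1
        xy = project_lonlat([134.0, 135.0], [7.0, 8.0])
        assert np.ptp(xy[:, 0]) > 1e5 and np.ptp(xy[:, 1]) > 1e5


class TestEmpiricalSemivariogram:
    def test_single_pair_definition(self):
        # isolated close pair (4, 8) in the first bin: gamma = 0.5*(4-8)^2
        s = SpatialSample([[0, 0], [10, 0], [10000, 0]], [4.0, 8.0, 6.0])
        emp = empirical_semivariogram(s, bin_edges=[0, 20, 9000, 11000])
        first = emp.iloc[0]
        assert first["count"] == 1
        assert first["gamma"] == pytest.approx(8.0)

    def test_constant_field_is_zero_everywhere(self):
        rng = np.random.default_rng(0)
        s = SpatialSample(rng.uniform(0, 100, (20, 2)), np.full(20, 3.3))
        emp = empirical_semivariogram(s, n_lags=5)
        assert np.allclose(emp["gamma"].dropna(), 0.0)

    def test_iid_field_is_flat_at_the_variance(self):
        # pure-nugget oracle: gamma(h) ~ sigma^2 at all lags
        rng = np.random.default_rng(1)
        s = SpatialSample(rng.uniform(0, 1000, (400, 2)),
                          rng.normal(0, 2.0, 400))
        emp = empirical_semivariogram(s, n_lags=8)
        good = emp[emp["count"] > 50]
        assert np.all(np.abs(good["gamma"] - 4.0) / 4.0 < 0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            empirical_semivariogram(SpatialSample([[0, 0], [1, 1]], [1.0, 2.0]))

    def test_empty_bins_flagged_not_fabricated(self):
        s = SpatialSample([[0, 0], [1, 0], [1000, 0]], [1.0, 2.0, 3.0])
        emp = empirical_semivariogram(s, bin_edges=[0, 5, 500, 1100])
        gap = emp.iloc[1]
        assert gap["count"] == 0 and np.isnan(gap["gamma"])

    def test_directional_output_per_bearing(self):
        rng = np.random.default_rng(2)
        s = SpatialSample(rng.uniform(0, 1000, (50, 2)), rng.normal(size=50))
        emp = empirical_semivariogram(s, n_lags=5, bearings=(0.0, 90.0))
        assert set(emp["bearing"]) == {0.0, 90.0}


class TestFitVariogram:
    def test_refit_own_curve_is_fixed_point(self):
        model = VariogramModel("exponential", 0.5, 4.0, 2000.0)
        h = np.linspace(100, 6000, 15)
        emp = pd.DataFrame({"bearing": "omni", "lag": h,
                            "gamma": model.gamma(h), "count": 100})
        fit = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.5, abs=1e-4)
        assert fit.partial_sill == pytest.approx(4.0, rel=1e-3)
        assert fit.range_m == pytest.approx(2000.0, rel=1e-3)

    def test_pure_nugget_degenerates_to_flat(self):
        rng = np.random.default_rng(3)
        s = SpatialSample(rng.uniform(0, 1000, (300, 2)),
                          rng.normal(0, 1.5, 300))
        emp = empirical_semivariogram(s, n_lags=8)
        fit = fit_variogram(emp, "exponential")
        # essentially all variance is in the flat component
        assert fit.gamma(1e6) == pytest.approx(2.25, rel=0.25)
        structure = fit.gamma(1e6) - fit.gamma(50.0)
        assert structure < 0.25 * fit.sill

    def test_auto_selects_lowest_rss(self):
        model = VariogramModel("spherical", 0.2, 3.0, 1500.0)
        h = np.linspace(100, 4000, 20)
        emp = pd.DataFrame({"bearing": "omni", "lag": h,
                            "gamma": model.gamma(h), "count": 50})
        fit = fit_variogram(emp, "auto")
        assert fit.family == "spherical"

    def test_wls_simulation_recovery_at_survey_scale(self):
        # median estimate over 8 replicate fields, nested close-pair design;
        # WLS resolves sill and range well, the nugget only coarsely
        true = VariogramModel("exponential", 0.5, 4.0, 2000.0)
        ests = []
        for rep in range(8):
            pts = synth.nested_sampling_points(66, (5.0, 500.0),
                                               seed=100 + rep, n_max=200)
            s = synth.generate_spatial_field(true, points=pts, seed=100 + rep)
            emp = empirical_semivariogram(
                s, bin_edges=np.r_[0, 25, np.linspace(400, 5000, 11)])
            try:
                f = fit_variogram(emp, "exponential")
            except kriging.VariogramFitError as exc:
                f = exc.best
            ests.append([f.nugget, f.partial_sill, f.range_m])
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(0.5, abs=0.5)     # nugget, coarse
        assert med[1] == pytest.approx(4.0, rel=0.35)
        assert med[2] == pytest.approx(2000.0, rel=0.5)

    def test_ml_recovery_tighter_than_wls(self):
        true = VariogramModel("exponential", 0.5, 4.0, 2000.0)
        ests = []
        for rep in range(8):
            pts = synth.nested_sampling_points(66, (5.0, 500.0),
                                               seed=100 + rep, n_max=200)
            s = synth.generate_spatial_field(true, points=pts, seed=100 + rep)
            f = fit_variogram_ml(s, "exponential")
            ests.append([f.nugget, f.partial_sill, f.range_m])
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(0.5, rel=0.25)
        assert med[1] == pytest.approx(4.0, rel=0.25)
        assert med[2] == pytest.approx(2000.0, rel=0.25)


class TestOrdinaryKriging:
    @pytest.fixture
    def sample(self):
        rng = np.random.default_rng(4)
        model = VariogramModel("exponential", 0.0, 2.0, 800.0)
        return synth.generate_spatial_field(model, n_points=40,
                                            domain=((0, 3000), (0, 3000)),
                                            seed=4), model

    def test_exact_interpolation_at_nugget_zero(self, sample):
        s, model = sample
        pred, var = ordinary_krige(s, model, s.points)
        assert np.allclose(pred, s.values, atol=1e-8)
        assert np.all(var < 1e-8)

    def test_weights_sum_to_one(self, sample):
        s, model = sample
        grid = make_grid(s, nx=15, ny=15)
        _, _, w = ordinary_krige(s, model, grid, return_weights=True)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_variance_nonnegative(self, sample):
        s, model = sample
        _, var = ordinary_krige(s, model, make_grid(s, nx=15, ny=15))
        assert np.all(var >= 0.0)

    def test_single_point_gives_constant_surface(self):
        s = SpatialSample([[0.0, 0.0]], [7.0])
        model = VariogramModel("exponential", 0.0, 1.0, 100.0)
        pred, _ = ordinary_krige(s, model, [[50.0, 50.0], [500.0, -100.0]])
        assert np.allclose(pred, 7.0)

    def test_two_point_system_matches_hand_solved_linear_algebra(self):
        # independent oracle: assemble and solve the 3x3 kriging system here
        model = VariogramModel("exponential", 0.3, 2.0, 1000.0)
        pts = np.array([[0.0, 0.0], [1000.0, 0.0]])
        vals = np.array([1.0, 3.0])
        target = np.array([[250.0, 0.0]])
        g = lambda h: model.gamma(h)  # noqa: E731
        A = np.array([[0.0, float(g(1000.0)), 1.0],
                      [float(g(1000.0)), 0.0, 1.0],
                      [1.0, 1.0, 0.0]])
        b = np.array([float(g(250.0)), float(g(750.0)), 1.0])
        w_hand = np.linalg.solve(A, b)
        pred, var, w = ordinary_krige(SpatialSample(pts, vals), model, target,
                                      return_weights=True)
        assert np.allclose(w[0], w_hand[:2], atol=1e-10)
        assert pred[0] == pytest.approx(w_hand[:2] @ vals)
        assert var[0] == pytest.approx(w_hand[:2] @ b[:2] + w_hand[2])

    def test_translation_and_rotation_invariance(self, sample):
        s, model = sample
        grid = make_grid(s, nx=8, ny=8)
        pred0, var0 = ordinary_krige(s, model, grid)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([12345.0, -6789.0])
        s2 = SpatialSample(s.points @ rot.T + shift, s.values)
        pred1, var1 = ordinary_krige(s2, model, grid @ rot.T + shift)
        assert np.allclose(pred0, pred1, atol=1e-7)
        assert np.allclose(var0, var1, atol=1e-7)

    def test_duplicate_points_are_averaged_on_ingest(self):
        s = SpatialSample([[0, 0], [0, 0], [10, 0], [500, 0]],
                          [1.0, 3.0, 5.0, 2.0])
        assert len(s) == 3
        assert 2.0 in s.values  # the coincident pair averaged


class TestAnisotropy:
    def test_isotropic_field_recommends_no_correction(self):
        model = VariogramModel("exponential", 0.2, 3.0, 1500.0)
        s = synth.generate_spatial_field(model, n_points=300,
                                         domain=((0, 10000), (0, 10000)),
                                         seed=5)
        diag = kriging.anisotropy_diagnostic(s)
        assert diag["correct"] is False
        assert diag["ratio"] == 1.0

    def test_anisotropic_transform_rescales_distances(self):
        model = VariogramModel("exponential", 0.0, 1.0, 1000.0,
                               anisotropy_ratio=0.5, anisotropy_angle_deg=0.0)
        pts = np.array([[0.0, 0.0], [0.0, 500.0], [500.0, 0.0]])
        out = model.transform(pts)
        # the minor (y) axis stretches by 1/ratio
        assert np.hypot(*(out[1] - out[0])) == pytest.approx(1000.0)
        assert np.hypot(*(out[2] - out[0])) == pytest.approx(500.0)
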