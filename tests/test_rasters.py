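"""Elemental raster layer: StDM fit/predict, random fields, polygon stats."""

import numpy as np
import pandas as pd
import pytest
import shapely

import stoichscape as ss
from stoichscape.exceptions import (
    EmptyRegionError,
    SingularityError,
    UndefinedStatisticError,
    ValidationError,
)
from stoichscape.rasters import CovariateStack


def _flat_stack(n=20, elevation=100.0):
    shape = (n, n)
    return CovariateStack(
        origin_x=0.0,
        origin_y=0.0,
        pixel_size=30.0,
        continuous={
            "normalized_aspect": np.zeros(shape),
            "slope": np.zeros(shape),
            "elevation": np.full(shape, elevation),
        },
    )


class TestPredictStdm:
    def test_zero_coefficients_give_constant_intercept_surface(self):
        model = ss.StDMModel("nitrogen_pct", intercept=2.78, coefficients={
            "normalized_aspect": 0.0, "slope": 0.0, "elevation": 0.0})
        raster = ss.predict_stdm(model, _flat_stack())
        assert np.allclose(raster.values, 2.78)

    def test_linear_arithmetic_in_elevation(self):
        model = ss.StDMModel("carbon_log_quantity", intercept=0.0,
                             coefficients={"elevation": 0.01})
        raster = ss.predict_stdm(model, _flat_stack(elevation=100.0))
        assert np.allclose(raster.values, 1.0)

    def test_nodata_propagates_from_covariates(self):
        stack = _flat_stack(5)
        stack.nodata_mask[0, 0] = True
        model = ss.StDMModel("nitrogen_pct", 1.0, {"elevation": 0.0})
        raster = ss.predict_stdm(model, stack)
        assert raster.nodata_mask[0, 0]

    def test_unknown_categorical_level_rejected(self):
        stack = _flat_stack(5)
        model = ss.StDMModel("nitrogen_pct", 1.0, {"landcover[bog]": 2.0})
        with pytest.raises(ValidationError):
            ss.predict_stdm(model, stack)


class TestFitStdm:
    def test_noiseless_linear_response_recovered_exactly(self, rng):
        elev = rng.uniform(0, 500, 200)
        plots = pd.DataFrame({
            "normalized_aspect": rng.uniform(-1, 1, 200),
            "slope": rng.uniform(0, 30, 200),
            "elevation": elev,
            "nitrogen_pct": 2.0 + 0.004 * elev,
        })
        model = ss.fit_stdm(plots, "nitrogen_pct")
        assert model.coefficients["elevation"] == pytest.approx(0.004, abs=1e-10)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        elev = rng.uniform(0, 500, 50)
        plots = pd.DataFrame({
            "elevation": elev,
            "slope": 2.0 * elev,  # perfectly collinear
            "nitrogen_pct": rng.normal(2.8, 0.3, 50),
        })
        with pytest.raises(SingularityError, match="slope|elevation"):
            ss.fit_stdm(plots, "nitrogen_pct", continuous=("elevation", "slope"))

    def test_refit_r2_matches_nitrogen_stdm_strength(self, rng):
        # 106 plots generated at R^2 = 0.31 (signal/total variance ratio)
        n = 106
        beta, sd_x = 0.004, 100.0
        signal_var = (beta * sd_x) ** 2
        noise_var = signal_var * (1 - 0.31) / 0.31
        elev = rng.normal(300, sd_x, n)
        y = 2.0 + beta * elev + rng.normal(0, np.sqrt(noise_var), n)
        plots = pd.DataFrame({"elevation": elev, "nitrogen_pct": y})
        model = ss.fit_stdm(plots, "nitrogen_pct", continuous=("elevation",))
        assert model.r_squared == pytest.approx(0.31, abs=0.15)

    def test_simulate_then_refit_r2_within_tolerance(self, rng):
        # 10,000 cells from a known model with residual_sd 0.2; brute-force
        # variance decomposition gives the generating R^2
        n = 10_000
        elev = rng.uniform(0, 500, n)
        aspect = rng.uniform(-1, 1, n)
        truth = ss.StDMModel("nitrogen_pct", 2.0,
                             {"elevation": 0.002, "normalized_aspect": 0.15},
                             residual_sd=0.2)
        mu = 2.0 + 0.002 * elev + 0.15 * aspect
        y = mu + rng.normal(0, 0.2, n)
        gen_r2 = np.var(mu) / (np.var(mu) + 0.2**2)
        plots = pd.DataFrame(
            {"elevation": elev, "normalized_aspect": aspect, "nitrogen_pct": y})
        model = ss.fit_stdm(plots, "nitrogen_pct",
                            continuous=("elevation", "normalized_aspect"))
        assert model.r_squared == pytest.approx(gen_r2, abs=0.1)
        assert model.residual_sd == pytest.approx(truth.residual_sd, rel=0.05)

    def test_coefficient_coverage_over_replicates(self, rng):
        # recovered within 3 SE in >= 95% of 500 replicates
        n, beta_true, sd_noise = 106, 0.004, 0.2
        hits = 0
        for _ in range(500):
            elev = rng.normal(300, 100, n)
            y = 2.0 + beta_true * elev + rng.normal(0, sd_noise, n)
            plots = pd.DataFrame({"elevation": elev, "nitrogen_pct": y})
            m = ss.fit_stdm(plots, "nitrogen_pct", continuous=("elevation",))
            X = np.column_stack([np.ones(n), elev])
            se = m.residual_sd * np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
            hits += abs(m.coefficients["elevation"] - beta_true) <= 3 * se
        assert hits / 500 >= 0.95

    def test_fit_predict_round_trip_reproduces_fitted_values(self, rng):
        n = 12
        stack = CovariateStack(
            0.0, 0.0, 30.0,
            continuous={"elevation": rng.uniform(0, 500, (n, n)),
                        "slope": rng.uniform(0, 30, (n, n))},
            categorical={"landcover": rng.integers(0, 2, (n, n))},
            levels={"landcover": ("coniferous", "other")},
        )
        frame = stack.to_frame()
        frame["nitrogen_pct"] = (
            2.0 + 0.002 * frame["elevation"] - 0.01 * frame["slope"]
            + 0.3 * (frame["landcover"] == "other")
            + rng.normal(0, 0.1, len(frame))
        )
        model = ss.fit_stdm(frame, "nitrogen_pct", continuous=("elevation", "slope"),
                            categorical_levels={"landcover": ("coniferous", "other")})
        raster = ss.predict_stdm(model, stack)  # noise disabled
        X = np.column_stack([
            np.ones(len(frame)), frame["elevation"], frame["slope"],
            (frame["landcover"] == "other").astype(float)])
        beta = np.array([model.intercept, model.coefficients["elevation"],
                         model.coefficients["slope"],
                         model.coefficients["landcover[other]"]])
        assert np.allclose(raster.values.ravel(), X @ beta, atol=1e-10)


class TestSimulateElementalPair:
    def test_pooled_landscape_targets_hit_exactly(self):
        rc, rn = ss.simulate_elemental_pair(
            200, 200, target_mean_c=-1.65, target_sd_c=0.89,
            target_mean_n=2.78, target_sd_n=0.28, target_corr=-0.01, seed=5)
        assert rc.values.mean() == pytest.approx(-1.65, rel=0.02)
        assert rc.values.std() == pytest.approx(0.89, rel=0.02)
        assert rn.values.mean() == pytest.approx(2.78, rel=0.02)
        assert rn.values.std() == pytest.approx(0.28, rel=0.02)
        r = np.corrcoef(rc.values.ravel(), rn.values.ravel())[0, 1]
        assert r == pytest.approx(-0.01, abs=0.05)

    def test_degenerate_sd_gives_constant_raster(self):
        rc, _ = ss.simulate_elemental_pair(50, 50, target_sd_c=0.0, target_corr=0.0, seed=0)
        assert np.all(rc.values == rc.values[0, 0])

    def test_impossible_correlation_with_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            ss.simulate_elemental_pair(50, 50, target_sd_c=0.0, target_corr=0.5, seed=0)

    def test_white_noise_high_correlation_brute_force(self):
        rc, rn = ss.simulate_elemental_pair(
            100, 100, target_corr=0.9, spatial_range=0.0, seed=3)
        r = np.corrcoef(rc.values.ravel(), rn.values.ravel())[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_statistics_converge_with_grid_size(self):
        for n in (60, 240):
            rc, rn = ss.simulate_elemental_pair(n, n, target_corr=0.4, seed=n)
            r = np.corrcoef(rc.values.ravel(), rn.values.ravel())[0, 1]
            assert r == pytest.approx(0.4, abs=0.05)
            assert rc.values.mean() == pytest.approx(-1.65, rel=0.02)


class TestPolygonStats:
    def test_constant_raster(self):
        r = ss.ElementalRaster(0, 0, 30, np.full((10, 10), 5.0))
        poly = shapely.box(0, 0, 300, 300)
        mean, median, sd, n = ss.polygon_stats(r, poly)
        assert (mean, median, sd, n) == (5.0, 5.0, 0.0, 100)

    def test_two_by_two_hand_arithmetic(self):
        r = ss.ElementalRaster(0, 0, 30, np.array([[1.0, 2.0], [3.0, 4.0]]))
        mean, median, sd, n = ss.polygon_stats(r, shapely.box(0, 0, 60, 60))
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert n == 4

    def test_matches_exhaustive_cell_center_enumeration(self, rng):
        vals = rng.normal(size=(40, 40))
        mask = rng.random((40, 40)) < 0.1
        r = ss.ElementalRaster(0, 0, 30, vals, mask)
        poly = shapely.Polygon([(50, 40), (1100, 200), (900, 1100), (100, 800)])
        collected = []
        for i in range(40):
            for j in range(40):
                if mask[i, j]:
                    continue
                p = shapely.Point((j + 0.5) * 30, (i + 0.5) * 30)
                if poly.covers(p):
                    collected.append(vals[i, j])
        mean, median, sd, n = ss.polygon_stats(r, poly)
        assert n == len(collected)
        assert mean == pytest.approx(np.mean(collected))
        assert median == pytest.approx(np.median(collected))
        assert sd == pytest.approx(np.std(collected, ddof=1))

    def test_empty_region_raises(self):
        r = ss.ElementalRaster(0, 0, 30, np.zeros((5, 5)))
        with pytest.raises(EmptyRegionError):
            ss.polygon_stats(r, shapely.box(10_000, 10_000, 10_100, 10_100))


class TestPearsonCN:
    def test_identical_layers_give_r_one(self, rng):
        vals = rng.normal(size=(20, 20))
        rc = ss.ElementalRaster(0, 0, 30, vals, measure="carbon_log_quantity")
        rn = ss.ElementalRaster(0, 0, 30, vals.copy(), measure="nitrogen_pct")
        assert ss.pearson_cn(rc, rn, shapely.box(0, 0, 600, 600)) == pytest.approx(1.0)

    def test_negated_layer_gives_r_minus_one(self, rng):
        vals = rng.normal(size=(20, 20))
        rc = ss.ElementalRaster(0, 0, 30, vals)
        rn = ss.ElementalRaster(0, 0, 30, -vals, measure="nitrogen_pct")
        assert ss.pearson_cn(rc, rn, shapely.box(0, 0, 600, 600)) == pytest.approx(-1.0)

    def test_independent_fields_near_zero(self, rng):
        rc = ss.ElementalRaster(0, 0, 30, rng.normal(size=(100, 100)))
        rn = ss.ElementalRaster(0, 0, 30, rng.normal(size=(100, 100)),
                                measure="nitrogen_pct")
        assert abs(ss.pearson_cn(rc, rn, shapely.box(0, 0, 3000, 3000))) < 0.05

    def test_zero_variance_is_undefined(self):
        rc = ss.ElementalRaster(0, 0, 30, np.full((5, 5), 1.0))
        rn = ss.ElementalRaster(0, 0, 30, np.arange(25.0).reshape(5, 5),
                                measure="nitrogen_pct")
        with pytest.raises(UndefinedStatisticError):
            ss.pearson_cn(rc, rn, shapely.box(0, 0, 150, 150))


class TestGridIO:
    def test_round_trip_preserves_values_and_mask(self, tmp_path, rng):
        vals = rng.normal(size=(15, 12))
        mask = rng.random((15, 12)) < 0.2
        r = ss.ElementalRaster(120.0, -300.0, 30.0, vals, mask, "nitrogen_pct")
        ss.write_grid(r, tmp_path / "r.grid")
        back = ss.read_grid(tmp_path / "r.grid")
        assert back.same_grid(r)
        assert back.measure == r.measure
        assert np.array_equal(back.nodata_mask, mask)
        assert np.allclose(back.values[~mask], vals[~mask])
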