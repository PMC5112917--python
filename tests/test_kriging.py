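"""Variogram estimation/fitting and ordinary kriging against brute-force oracles."""

import numpy as np
import pytest

from moltrace import (
    EmpiricalVariogram,
    VariogramModel,
    compare_surfaces_by_validation,
    empirical_variogram,
    fit_variogram,
    krige,
    loo_cross_validate,
    make_grid_template,
)
from moltrace.geo import pairwise_km
from moltrace.isoscape_kriging import aicc_from_rss, kriging_weights_at
from moltrace.raster_io import FeatherSample


def test_two_point_semivariance_closed_form():
    ev = empirical_variogram([(45.0, -100.0), (45.0, -99.0)], [0.0, 2.0], lag_km=100.0, n_lags=2)
    # single pair: gamma = (1/2) * (2 - 0)^2 / 1 = 2
    assert ev.semivariance.tolist() == [2.0]
    assert ev.pair_counts.tolist() == [1]


def test_constant_field_has_zero_semivariance():
    rng = np.random.default_rng(0)
    pts = [(45 + rng.uniform(0, 2), -100 + rng.uniform(0, 2)) for _ in range(15)]
    ev = empirical_variogram(pts, np.full(15, -80.0), lag_km=40.0, n_lags=8)
    assert np.allclose(ev.semivariance, 0.0)


def test_fit_recovers_exact_model_curve():
    """WLS fit on noiseless curve samples returns the generating parameters."""
    truth = VariogramModel("stable", nugget=132.01, partial_sill=380.20, range_param=718.0, shape=1.5)
    lags = np.linspace(40, 1200, 25)
    ev = EmpiricalVariogram(
        lag_centers=lags,
        semivariance=truth.gamma(lags),
        pair_counts=np.full(25, 50),
        max_distance=1200.0,
    )
    fit = fit_variogram(ev, "stable")
    assert fit.nugget == pytest.approx(truth.nugget, rel=0.01)
    assert fit.partial_sill == pytest.approx(truth.partial_sill, rel=0.01)
    assert fit.range_param == pytest.approx(truth.range_param, rel=0.01)
    assert fit.shape == pytest.approx(truth.shape, rel=0.01)


def test_pure_nugget_data_fit_is_flat():
    lags = np.linspace(30, 600, 12)
    ev = EmpiricalVariogram(lags, np.full(12, 50.0), np.full(12, 30), 600.0)
    fit = fit_variogram(ev, "stable")
    # flat variogram: the structured part contributes almost nothing
    assert fit.partial_sill * (1 - np.exp(-3)) < 0.05 * 50.0 or fit.nugget > 0.9 * 50.0
    assert np.allclose(fit.gamma(lags), 50.0, rtol=0.05)


def _brute_force_ok(points, values, model, target):
    """Independent semivariance-form solve of the ordinary kriging system."""
    lats = np.array([p[0] for p in points])
    lons = np.array([p[1] for p in points])
    n = len(points)
    from moltrace.geo import haversine_km

    G = model.gamma(pairwise_km(lats, lons))
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    g0 = model.gamma(haversine_km(lats, lons, target[0], target[1]))
    b = np.concatenate([g0, [1.0]])
    sol = np.linalg.solve(A, b)
    w = sol[:n]
    pred = float(w @ np.asarray(values))
    var = float(w @ g0 + sol[n])
    return w, pred, var


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kriging_matches_brute_force_system(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 10)
    pts = [(45 + rng.uniform(0, 3), -102 + rng.uniform(0, 4)) for _ in range(n)]
    vals = rng.uniform(-120, -60, n)
    model = VariogramModel("stable", nugget=20.0, partial_sill=300.0, range_param=400.0, shape=1.3)
    target = (46.2, -100.3)
    w, pred, var = kriging_weights_at(pts, vals, model, target)
    w_bf, pred_bf, var_bf = _brute_force_ok(pts, vals, model, target)
    assert np.allclose(w, w_bf, atol=1e-8)
    assert pred == pytest.approx(pred_bf, abs=1e-8)
    assert var == pytest.approx(var_bf, abs=1e-6)
    assert w.sum() == pytest.approx(1.0, abs=1e-8)


def test_zero_nugget_interpolates_exactly():
    rng = np.random.default_rng(3)
    pts = [(44 + rng.uniform(0, 3), -103 + rng.uniform(0, 4)) for _ in range(8)]
    vals = rng.uniform(-120, -60, 8)
    model = VariogramModel("stable", nugget=0.0, partial_sill=250.0, range_param=500.0, shape=1.5)
    for p, v in zip(pts, vals):
        _, pred, var = kriging_weights_at(pts, vals, model, p)
        assert pred == pytest.approx(v, abs=1e-8)
        assert var == pytest.approx(0.0, abs=1e-6)


def test_constant_data_gives_constant_surface():
    pts = [(44.0, -103.0), (45.5, -101.0), (46.0, -99.5)]
    model = VariogramModel("stable", nugget=0.0, partial_sill=100.0, range_param=300.0)
    tmpl = make_grid_template((43.5, 46.5, -103.5, -99.0), 0.5)
    surf, sd = krige(pts, [-80.0, -80.0, -80.0], model, tmpl)
    assert np.allclose(surf.values, -80.0, atol=1e-8)


def test_duplicate_points_averaged_with_warning():
    pts = [(44.0, -103.0), (44.0, -103.0), (46.0, -99.5)]
    model = VariogramModel("stable", nugget=0.0, partial_sill=100.0, range_param=300.0)
    tmpl = make_grid_template((43.5, 46.5, -103.5, -99.0), 1.0)
    with pytest.warns(UserWarning, match="duplicate"):
        surf, _ = krige(pts, [-70.0, -90.0, -60.0], model, tmpl)
    assert np.isfinite(surf.values).all()


def test_loo_rmse_tracks_noise_sd():
    """On a spatially unstructured field the LOO error approaches the noise SD."""
    rng = np.random.default_rng(4)
    pts = [(44 + rng.uniform(0, 4), -104 + rng.uniform(0, 6)) for _ in range(40)]
    noise_sd = 6.0
    vals = -90 + rng.normal(0, noise_sd, 40)
    model = VariogramModel("stable", nugget=noise_sd**2, partial_sill=1e-6, range_param=300.0)
    rmse, resid = loo_cross_validate(pts, vals, model)
    assert len(resid) == 40
    assert rmse == pytest.approx(noise_sd, rel=0.35)


def test_outlier_inflates_loo_rmse_monotonically():
    rng = np.random.default_rng(5)
    pts = [(44 + rng.uniform(0, 4), -104 + rng.uniform(0, 6)) for _ in range(15)]
    base = list(-90 + rng.normal(0, 3, 15))
    model = VariogramModel("stable", nugget=9.0, partial_sill=50.0, range_param=300.0)
    rmses = []
    for bump in (0.0, 15.0, 30.0):
        vals = list(base)
        vals[0] += bump
        rmses.append(loo_cross_validate(pts, vals, model)[0])
    assert rmses[0] < rmses[1] < rmses[2]


def test_aicc_closed_form():
    # n=10, RSS=10, k=3: 10*ln(1) + 6 + 24/6 = 10
    assert aicc_from_rss(10, 10.0, 3) == pytest.approx(10.0)


def _holdout_birds(grid, rng, n, noise_sd):
    lat_min, lat_max, lon_min, lon_max = grid.extent
    birds = []
    for i in range(n):
        lat = rng.uniform(lat_min + 0.1, lat_max - 0.1)
        lon = rng.uniform(lon_min + 0.1, lon_max - 0.1)
        r, c = grid.index_of(lat, lon)
        birds.append(
            FeatherSample(f"h{i}", f"hs{i}", lat, lon, "SIM", "spring",
                          d2h=float(grid.values[r, c] + rng.normal(0, noise_sd)))
        )
    return birds


def test_identical_surfaces_split_weights_evenly(plane_grid):
    rng = np.random.default_rng(6)
    holdout = _holdout_birds(plane_grid, rng, 20, 3.0)
    res = compare_surfaces_by_validation([plane_grid, plane_grid], holdout)
    assert np.allclose(res.weights, [0.5, 0.5])


def test_truth_surface_wins_against_corrupted(plane_grid):
    rng = np.random.default_rng(7)
    holdout = _holdout_birds(plane_grid, rng, 30, 2.0)
    corrupted = plane_grid.copy_with(plane_grid.values + rng.normal(0, 25, plane_grid.shape))
    res = compare_surfaces_by_validation([plane_grid, corrupted], holdout)
    assert res.chosen == 0
    assert res.weights[0] > 0.95
    assert res.r_squared > 0.5


def test_validation_slope_ci_covers_unity(plane_grid):
    """On well-specified data the 85% CI of observed~predicted covers 1."""
    rng = np.random.default_rng(8)
    covered = 0
    n_rep = 20
    for _ in range(n_rep):
        holdout = _holdout_birds(plane_grid, rng, 30, 3.0)
        res = compare_surfaces_by_validation([plane_grid, plane_grid.copy_with(plane_grid.values * 1.0)], holdout)
        lo, hi = res.slope_ci85
        covered += int(lo <= 1.0 <= hi)
    assert covered / n_rep >= 0.8 - 0.15  # 85% nominal minus Monte-Carlo slack
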