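"""Ordinary kriging of feather d2H with variogram model selection.

Spatial structure of site-mean feather d2H is summarised by an empirical
(Matheron) semivariogram on great-circle distances, a stable or Gaussian
variogram model is fitted by weighted least squares, and site means are
interpolated onto a grid by ordinary point kriging (weights constrained to
sum to one through a Lagrange multiplier). Competing kriged surfaces are
compared on an independent holdout by AICc of the observed-versus-predicted
regression.

The stable model is parameterised with the "effective range" convention:
gamma(h) = nugget + psill * (1 - exp(-3 (h/range)^shape)), so the curve
reaches ~95% of the sill at ``range_param``. The Gaussian model is the
shape = 2 special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geo import haversine_km, pairwise_km
from .raster_io import FeatherSample, IsotopeGrid

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "SurfaceComparison",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "loo_cross_validate",
    "compare_surfaces_by_validation",
    "make_grid_template",
]


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariance estimate (permil^2 versus km)."""

    lag_centers: np.ndarray      # km
    semivariance: np.ndarray     # permil^2
    pair_counts: np.ndarray
    max_distance: float          # km
    direction: tuple[float, float] | None = None  # (azimuth deg, tolerance deg)


@dataclass(frozen=True)
class VariogramModel:
    """Stable / Gaussian variogram with nugget, partial sill and range."""

    kind: str                    # "stable" | "gaussian"
    nugget: float                # permil^2
    partial_sill: float          # permil^2
    range_param: float           # km (effective range)
    shape: float = 1.0           # stable exponent in (0, 2]
    anisotropy: tuple[float, float] | None = None  # (major azimuth deg, ratio)

    def __post_init__(self) -> None:
        if self.kind not in {"stable", "gaussian"}:
            raise ValueError("kind must be 'stable' or 'gaussian'")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ValueError("nugget/partial_sill must be >= 0 and range > 0")
        if not 0 < self.shape <= 2:
            raise ValueError("shape must lie in (0, 2]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at separation h (km); gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        shape = 2.0 if self.kind == "gaussian" else self.shape
        structure = 1.0 - np.exp(-3.0 * (h / self.range_param) ** shape)
        out = self.nugget + self.partial_sill * structure
        return np.where(h > 0, out, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) (nugget at h=0 only)."""
        h = np.asarray(h, dtype=float)
        shape = 2.0 if self.kind == "gaussian" else self.shape
        c = self.partial_sill * np.exp(-3.0 * (h / self.range_param) ** shape)
        return np.where(h > 0, c, self.partial_sill + self.nugget)


def empirical_variogram(
    points: list[tuple[float, float]],
    values,
    lag_km: float,
    n_lags: int = 12,
    direction: tuple[float, float] | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) per lag bin.

    ``direction=(azimuth, tolerance)`` restricts pairs to those whose
    bearing lies within the tolerance of the azimuth (for anisotropy
    diagnostics); the default uses all pairs (isotropic).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    values = np.asarray(values, dtype=float)
    lats = np.array([p[0] for p in points])
    lons = np.array([p[1] for p in points])
    dist = pairwise_km(lats, lons)
    iu = np.triu_indices(len(points), k=1)
    d = dist[iu]
    dz2 = (values[iu[0]] - values[iu[1]]) ** 2
    if direction is not None:
        azimuth, tol = direction
        bearing = _bearing_deg(lats[iu[0]], lons[iu[0]], lats[iu[1]], lons[iu[1]])
        delta = np.minimum(
            np.abs((bearing - azimuth) % 180.0), np.abs((azimuth - bearing) % 180.0)
        )
        keep = delta <= tol
        d, dz2 = d[keep], dz2[keep]
    max_distance = lag_km * n_lags
    if d.size == 0 or d.min() > max_distance:
        raise ValueError("no point pairs within the variogram's maximum distance")
    centers, gammas, counts = [], [], []
    for k in range(n_lags):
        lo, hi = k * lag_km, (k + 1) * lag_km
        mask = (d > lo) & (d <= hi)
        if not mask.any():
            continue
        centers.append((lo + hi) / 2)
        gammas.append(dz2[mask].sum() / (2 * mask.sum()))
        counts.append(int(mask.sum()))
    return EmpiricalVariogram(
        lag_centers=np.array(centers),
        semivariance=np.array(gammas),
        pair_counts=np.array(counts),
        max_distance=max_distance,
        direction=direction,
    )


def _bearing_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def fit_variogram(ev: EmpiricalVariogram, kind: str = "stable") -> VariogramModel:
    """Weighted least squares fit with Cressie-style weights N(h)/gamma_model^2.

    A small multi-start over range and shape guards against local optima;
    non-convergence raises with the optimizer diagnostics attached.
    """
    if len(ev.lag_centers) < 3:
        raise ValueError("need at least 3 usable lags to fit a variogram")
    h = ev.lag_centers
    g = ev.semivariance
    counts = ev.pair_counts.astype(float)
    var0 = max(g.max(), 1e-12)
    fit_shape = kind == "stable"

    def residuals(theta):
        nugget, psill, rng_ = theta[:3]
        shape = theta[3] if fit_shape else 2.0
        model = VariogramModel(kind=kind, nugget=max(nugget, 0.0),
                               partial_sill=max(psill, 1e-12),
                               range_param=max(rng_, 1e-6),
                               shape=min(max(shape, 1e-2), 2.0))
        gm = model.gamma(h)
        w = np.sqrt(counts) / np.maximum(gm, 1e-8)
        return w * (gm - g)

    best = None
    h_max = ev.max_distance
    starts = []
    for r0 in (h_max / 4, h_max / 2, h_max):
        for s0 in ((0.5, 1.0, 1.5, 2.0) if fit_shape else (2.0,)):
            starts.append((0.1 * var0, var0, r0, s0))
    lower = [0.0, 1e-9, 1e-3] + ([0.05] if fit_shape else [])
    upper = [2 * var0, 5 * var0, 10 * h_max] + ([2.0] if fit_shape else [])
    for x0 in starts:
        x0 = x0[:3] + ((x0[3],) if fit_shape else ())
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lower, upper), max_nfev=2000)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("variogram fit failed to converge from any start")
    nugget, psill, rng_ = best.x[:3]
    shape = float(best.x[3]) if fit_shape else 2.0
    return VariogramModel(kind=kind, nugget=float(max(nugget, 0.0)),
                          partial_sill=float(max(psill, 0.0)) or 1e-12,
                          range_param=float(rng_), shape=shape)


# ---------------------------------------------------------------------------
# ordinary kriging


def _dedup(lats, lons, values):
    """Average values at duplicate coordinates (singular system otherwise)."""
    seen: dict[tuple[float, float], list[float]] = {}
    order: list[tuple[float, float]] = []
    for la, lo, v in zip(lats, lons, values):
        key = (round(float(la), 9), round(float(lo), 9))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(float(v))
    if len(order) < len(lats):
        warnings.warn("duplicate point locations averaged before kriging")
    la = np.array([k[0] for k in order])
    lo = np.array([k[1] for k in order])
    v = np.array([np.mean(seen[k]) for k in order])
    return la, lo, v


def _kriging_system(lats, lons, model: VariogramModel) -> np.ndarray:
    n = len(lats)
    d = pairwise_km(lats, lons)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.covariance(d)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def krige(
    points: list[tuple[float, float]],
    values,
    model: VariogramModel,
    grid_spec: IsotopeGrid,
) -> tuple[IsotopeGrid, IsotopeGrid]:
    """Ordinary point kriging onto the cells of a template grid.

    Returns (prediction grid, kriging SD grid). All data points are used at
    every cell (a global neighbourhood; the calibration networks here are
    small). With a zero nugget the predictor interpolates the data exactly.
    """
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points to krige")
    lats = np.array([p[0] for p in points])
    lons = np.array([p[1] for p in points])
    lats, lons, values = _dedup(lats, lons, values)
    n = len(lats)
    A = _kriging_system(lats, lons, model)
    cell_lats, cell_lons = grid_spec.cell_centers()
    glat = np.repeat(cell_lats, len(cell_lons))
    glon = np.tile(cell_lons, len(cell_lats))
    # covariance of each datum with each prediction cell
    d0 = haversine_km(lats[:, None], lons[:, None], glat[None, :], glon[None, :])
    B = np.empty((n + 1, d0.shape[1]))
    B[:n] = model.covariance(np.where(d0 > 0, d0, np.inf))
    # a cell exactly at a datum: covariance includes the nugget only if the
    # prediction is of the *measured* value; OK convention keeps C(0+)=psill,
    # giving exact interpolation only when nugget = 0
    B[:n][d0 == 0] = model.partial_sill
    B[n] = 1.0
    sol = np.linalg.solve(A, B)
    w = sol[:n]
    mu = sol[n]
    pred = w.T @ values
    c0 = model.partial_sill + model.nugget
    var = c0 - np.einsum("ij,ij->j", w, B[:n]) - mu
    var = np.maximum(var, 0.0)
    nrows, ncols = grid_spec.shape
    return (
        grid_spec.copy_with(pred.reshape(nrows, ncols)),
        grid_spec.copy_with(np.sqrt(var).reshape(nrows, ncols)),
    )


def kriging_weights_at(
    points: list[tuple[float, float]],
    values,
    model: VariogramModel,
    target: tuple[float, float],
) -> tuple[np.ndarray, float, float]:
    """(weights, prediction, kriging variance) at a single location.

    Exposed for verification against a direct solve of the kriging linear
    system on small instances.
    """
    lats = np.array([p[0] for p in points])
    lons = np.array([p[1] for p in points])
    values = np.asarray(values, dtype=float)
    n = len(lats)
    A = _kriging_system(lats, lons, model)
    d0 = haversine_km(lats, lons, target[0], target[1])
    b = np.empty(n + 1)
    b[:n] = np.where(d0 > 0, model.covariance(np.where(d0 > 0, d0, np.inf)), model.partial_sill)
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    w, mu = sol[:n], sol[n]
    pred = float(w @ values)
    var = float(model.sill - w @ b[:n] - mu)
    return w, pred, max(var, 0.0)


def loo_cross_validate(
    points: list[tuple[float, float]],
    values,
    model: VariogramModel,
) -> tuple[float, np.ndarray]:
    """Leave-one-out kriging RMSE; returns (rmse, per-point residuals)."""
    values = np.asarray(values, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points for cross-validation")
    residuals = np.empty(len(points))
    for i in range(len(points)):
        rest = [p for j, p in enumerate(points) if j != i]
        rest_v = np.delete(values, i)
        _, pred, _ = kriging_weights_at(rest, rest_v, model, points[i])
        residuals[i] = values[i] - pred
    return float(np.sqrt(np.mean(residuals**2))), residuals


# ---------------------------------------------------------------------------
# surface comparison on a holdout


@dataclass(frozen=True)
class SurfaceComparison:
    """AICc comparison of candidate surfaces on holdout birds."""

    aicc: np.ndarray
    weights: np.ndarray
    chosen: int
    slope: float
    intercept: float
    slope_ci85: tuple[float, float]
    intercept_ci85: tuple[float, float]
    r_squared: float
    n_holdout: int


def aicc_from_rss(n: int, rss: float, k: int) -> float:
    """AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("holdout too small for AICc correction")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_surfaces_by_validation(
    surfaces: list[IsotopeGrid],
    holdout: list[FeatherSample],
) -> SurfaceComparison:
    """Pick among surfaces by AICc of observed ~ predicted on holdout birds.

    For each surface, observed holdout feather d2H is regressed on the
    surface prediction at the collection cell; AICc uses k = 3 (intercept,
    slope, residual variance). Holdout birds outside a surface (or on
    nodata) are excluded pairwise with a warning.
    """
    import statsmodels.api as sm
    from .raster_io import extract_at_points

    if len(surfaces) < 2:
        raise ValueError("need at least 2 candidate surfaces")
    if not holdout:
        raise ValueError("holdout must be nonempty")
    obs = np.array([s.d2h for s in holdout])
    pts = [(s.lat, s.lon) for s in holdout]
    preds, fits, aiccs = [], [], []
    k = 3
    for surf in surfaces:
        vals, flags = extract_at_points(surf, pts)
        ok = np.array([f == "ok" for f in flags])
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} holdout birds outside surface; excluded")
        if ok.sum() < k + 2:
            raise ValueError("too few usable holdout birds")
        X = sm.add_constant(vals[ok])
        fit = sm.OLS(obs[ok], X).fit()
        rss = float(fit.ssr)
        aiccs.append(aicc_from_rss(int(ok.sum()), rss, k))
        fits.append((fit, int(ok.sum())))
        preds.append(vals)
    aiccs = np.array(aiccs)
    delta = aiccs - aiccs.min()
    weights = np.exp(-delta / 2)
    weights = weights / weights.sum()
    chosen = int(np.argmin(aiccs))
    fit, n_used = fits[chosen]
    ci = fit.conf_int(alpha=0.15)  # 85% CI
    return SurfaceComparison(
        aicc=aiccs,
        weights=weights,
        chosen=chosen,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci85=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci85=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(fit.rsquared),
        n_holdout=n_used,
    )


def make_grid_template(
    extent: tuple[float, float, float, float], cell_size: float
) -> IsotopeGrid:
    """An all-zero grid covering (lat_min, lat_max, lon_min, lon_max)."""
    lat_min, lat_max, lon_min, lon_max = extent
    nrows = int(np.ceil((lat_max - lat_min) / cell_size))
    ncols = int(np.ceil((lon_max - lon_min) / cell_size))
    return IsotopeGrid(
        np.zeros((nrows, ncols)), origin_lon=lon_min, origin_lat=lat_max, cell_size=cell_size
    )
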