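"""Regression isoscape for feather d13C.

Feather d13C is modelled from feather d2H and the proportion of the
surrounding county planted to C4 crops. Four candidate OLS models (each
main effect alone, both, both plus interaction) are ranked by AICc; within
the confidence set (delta AICc <= 2) the least-parameterised model whose
coefficients' 85% confidence intervals all exclude zero is selected — the
85% screen matches the information-theoretic ranking and guards against
"pretending" parameters that enter only by adding ~2 to the deviance.
Site-mean residuals of the selected model are spatially interpolated and
added back to the regression prediction to form the final surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geo import haversine_km, pairwise_km
from .isoscape_kriging import (
    VariogramModel,
    aicc_from_rss,
    empirical_variogram,
    fit_variogram,
    krige,
)
from .raster_io import FeatherSample, IsotopeGrid

__all__ = [
    "CandidateModel",
    "CandidateModelSet",
    "fit_candidates",
    "residual_surface",
    "predict_d13c",
    "partial_prediction",
]

_FORMULAS: dict[str, tuple[str, ...]] = {
    "d2h": ("d2h",),
    "prop_c4": ("prop_c4",),
    "additive": ("d2h", "prop_c4"),
    "interaction": ("d2h", "prop_c4", "d2h:prop_c4"),
}


@dataclass(frozen=True)
class CandidateModel:
    name: str
    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    ci85: dict[str, tuple[float, float]]
    aicc: float
    delta: float = np.nan
    weight: float = np.nan

    @property
    def k(self) -> int:
        return len(self.terms) + 2  # + intercept + residual variance

    def screen_passes(self) -> bool:
        """True when every non-intercept 85% CI excludes zero."""
        return all(lo * hi > 0 for t, (lo, hi) in self.ci85.items() if t != "const")

    def predict(self, d2h, prop_c4) -> np.ndarray:
        d2h = np.asarray(d2h, dtype=float)
        prop_c4 = np.asarray(prop_c4, dtype=float)
        out = np.full(np.broadcast(d2h, prop_c4).shape, self.params["const"], dtype=float)
        for term in self.terms:
            if term == "d2h":
                out = out + self.params[term] * d2h
            elif term == "prop_c4":
                out = out + self.params[term] * prop_c4
            else:
                out = out + self.params[term] * d2h * prop_c4
        return out


@dataclass(frozen=True)
class CandidateModelSet:
    models: tuple[CandidateModel, ...]
    chosen: CandidateModel | None  # None: nothing survives the 85% screen

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.models])


def _design(term: str, d2h: np.ndarray, c4: np.ndarray) -> np.ndarray:
    if term == "d2h":
        return d2h
    if term == "prop_c4":
        return c4
    return d2h * c4


def _resolve_prop_c4(
    samples: Sequence[FeatherSample],
    prop_c4: Mapping[str, float] | Sequence[float],
) -> np.ndarray:
    if isinstance(prop_c4, Mapping):
        return np.array([float(prop_c4[s.site_id]) for s in samples])
    arr = np.asarray(prop_c4, dtype=float)
    if len(arr) != len(samples):
        raise ValueError("prop_c4 length does not match samples")
    return arr


def fit_candidates(
    samples: Sequence[FeatherSample],
    prop_c4: Mapping[str, float] | Sequence[float],
) -> CandidateModelSet:
    """Fit and rank the four candidate d13C regressions.

    ``prop_c4`` is either a site_id -> proportion mapping or a per-sample
    sequence. Requires n >= 10 birds with finite d13C, d2H and covariate.
    """
    import statsmodels.api as sm

    c4 = _resolve_prop_c4(samples, prop_c4)
    y = np.array([s.d13c if s.d13c is not None else np.nan for s in samples])
    d2h = np.array([s.d2h for s in samples])
    ok = np.isfinite(y) & np.isfinite(d2h) & np.isfinite(c4)
    y, d2h, c4 = y[ok], d2h[ok], c4[ok]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples with complete covariates")
    if np.std(d2h) > 0 and np.std(c4) > 0:
        r = float(np.corrcoef(d2h, c4)[0, 1])
        if abs(r) > 0.99:
            raise ValueError(f"covariates collinear (|r| = {abs(r):.3f} > 0.99)")
    models: list[CandidateModel] = []
    for name, terms in _FORMULAS.items():
        X = np.column_stack([np.ones(n)] + [_design(t, d2h, c4) for t in terms])
        if n <= X.shape[1] + 1:
            raise ValueError(f"model {name!r} saturated: n = {n}, parameters = {X.shape[1]}")
        fit = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # + residual variance
        aicc = aicc_from_rss(n, float(fit.ssr), k)
        labels = ("const",) + terms
        ci = fit.conf_int(alpha=0.15)
        models.append(
            CandidateModel(
                name=name,
                terms=terms,
                params={lab: float(v) for lab, v in zip(labels, fit.params)},
                bse={lab: float(v) for lab, v in zip(labels, fit.bse)},
                ci85={lab: (float(lo), float(hi)) for lab, (lo, hi) in zip(labels, ci)},
                aicc=aicc,
            )
        )
    aiccs = np.array([m.aicc for m in models])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    models = [
        CandidateModel(**{**m.__dict__, "delta": float(d), "weight": float(wi)})
        for m, d, wi in zip(models, delta, w)
    ]
    # confidence set, then least-parameterised member passing the 85% screen
    candidates = sorted(
        (m for m in models if m.delta <= 2.0), key=lambda m: (m.k, m.delta)
    )
    chosen = next((m for m in candidates if m.screen_passes()), None)
    return CandidateModelSet(models=tuple(models), chosen=chosen)


def residual_surface(
    samples: Sequence[FeatherSample],
    prop_c4: Mapping[str, float] | Sequence[float],
    model: CandidateModel,
    grid_spec: IsotopeGrid,
    method: str = "kriging",
) -> IsotopeGrid:
    """Interpolate site-mean residuals of the chosen model onto a grid.

    Default is ordinary kriging with a stable variogram fitted to the
    residuals; inverse-distance weighting (power 2) is used on request or
    as a fallback when the variogram fit fails. Cells farther than twice
    the maximum pairwise site distance carry no data support and are set
    to zero (the regression-only prediction).
    """
    c4 = _resolve_prop_c4(samples, prop_c4)
    by_site: dict[str, list[float]] = {}
    coords: dict[str, tuple[float, float]] = {}
    for s, c in zip(samples, c4):
        if s.d13c is None or not np.isfinite(c):
            continue
        resid = s.d13c - float(model.predict(s.d2h, c))
        by_site.setdefault(s.site_id, []).append(resid)
        coords[s.site_id] = (s.lat, s.lon)
    if len(by_site) < 3:
        raise ValueError("need residuals at >= 3 sites")
    pts = [coords[k] for k in by_site]
    vals = np.array([np.mean(v) for v in by_site.values()])
    lats = np.array([p[0] for p in pts])
    lons = np.array([p[1] for p in pts])
    dmax = float(pairwise_km(lats, lons).max())

    surface = None
    if method == "kriging":
        try:
            ev = empirical_variogram(pts, vals, lag_km=max(dmax / 10, 1.0), n_lags=10)
            vm = fit_variogram(ev, kind="stable")
            surface, _ = krige(pts, vals, vm, grid_spec)
        except Exception as exc:  # singular/degenerate residual structure
            warnings.warn(f"residual variogram failed ({exc}); falling back to IDW")
    if surface is None:
        surface = _idw(pts, vals, grid_spec, power=2.0)

    # zero out cells beyond the support radius
    cell_lats, cell_lons = grid_spec.cell_centers()
    glat = np.repeat(cell_lats, len(cell_lons))
    glon = np.tile(cell_lons, len(cell_lats))
    dnear = haversine_km(lats[:, None], lons[:, None], glat[None, :], glon[None, :]).min(axis=0)
    out = surface.values.reshape(-1)
    out[dnear > 2 * dmax] = 0.0
    return grid_spec.copy_with(out.reshape(grid_spec.shape))


def _idw(pts, vals, grid_spec: IsotopeGrid, power: float = 2.0) -> IsotopeGrid:
    lats = np.array([p[0] for p in pts])
    lons = np.array([p[1] for p in pts])
    cell_lats, cell_lons = grid_spec.cell_centers()
    glat = np.repeat(cell_lats, len(cell_lons))
    glon = np.tile(cell_lons, len(cell_lats))
    d = haversine_km(lats[:, None], lons[:, None], glat[None, :], glon[None, :])
    d = np.maximum(d, 1e-9)
    w = d**-power
    pred = (w * vals[:, None]).sum(axis=0) / w.sum(axis=0)
    # exact at (numerically) coincident cells
    hit = d.min(axis=0) < 1e-6
    if hit.any():
        pred[hit] = vals[np.argmin(d[:, hit], axis=0)]
    return grid_spec.copy_with(pred.reshape(grid_spec.shape))


def predict_d13c(
    d2h_grid: IsotopeGrid,
    prop_c4_grid: IsotopeGrid,
    model: CandidateModel,
    residuals: IsotopeGrid | None = None,
) -> IsotopeGrid:
    """Cellwise regression prediction plus (optionally) the residual surface."""
    if not d2h_grid.aligned_with(prop_c4_grid):
        raise ValueError("d2h and prop_c4 grids are misaligned")
    out = model.predict(d2h_grid.values, prop_c4_grid.values)
    if residuals is not None:
        if not d2h_grid.aligned_with(residuals):
            raise ValueError("residual surface misaligned with prediction grids")
        out = out + np.nan_to_num(residuals.values)
    return d2h_grid.copy_with(out)


def partial_prediction(
    model: CandidateModel,
    vary: str,
    values: np.ndarray,
    medians: dict[str, float],
) -> np.ndarray:
    """Prediction along one covariate with the other held at its median."""
    if vary == "d2h":
        return model.predict(values, np.full_like(np.asarray(values, float), medians["prop_c4"]))
    if vary == "prop_c4":
        return model.predict(np.full_like(np.asarray(values, float), medians["d2h"]), values)
    raise ValueError("vary must be 'd2h' or 'prop_c4'")
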