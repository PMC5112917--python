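"""Feather-isoscape calibration by bootstrap regression with error propagation.

A feather d2H isoscape is derived from a precipitation d2H isoscape through
an affine rescaling function fitted across known-origin calibration sites.
Uncertainty in both the site-level feather means and the precipitation
predictions is propagated by refitting ordinary least squares on many
simulated data sets (one per bootstrap replicate) in which site values are
redrawn from their reported means and SDs. The stored replicate
coefficients then feed a per-pixel pooled error surface that combines
between-individual scatter, isoscape prediction error and calibration
uncertainty in quadrature.

Note that drawing the predictor with its full reported SD each replicate
induces the classical errors-in-variables attenuation of the slope; this is
inherent to the procedure, not a defect of the implementation.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster_io import FeatherSample, IsotopeGrid, SiteSummary

__all__ = [
    "RescalingFunction",
    "ErrorModel",
    "load_calibration_sites",
    "screen_calibration_sites",
    "fit_rescaling_bootstrap",
    "apply_rescaling",
    "pooled_error_surface",
    "site_summaries_from_samples",
]

DEFAULT_SIGMA_IND = 8.4  # permil; mean of the site-level feather SDs


@dataclass(frozen=True)
class RescalingFunction:
    """Affine map d2H_f = intercept + slope * d2H_p with bootstrap spread."""

    intercept: float
    slope: float
    intercept_sd: float
    slope_sd: float
    draws: np.ndarray  # (n_boot, 2) columns (intercept, slope)

    @property
    def n_boot(self) -> int:
        return len(self.draws)

    def predict(self, d2h_p):
        return self.intercept + self.slope * np.asarray(d2h_p, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "intercept_sd": self.intercept_sd,
                    "slope_sd": self.slope_sd,
                    "draws": self.draws.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RescalingFunction":
        obj = json.loads(Path(path).read_text())
        return cls(
            intercept=obj["intercept"],
            slope=obj["slope"],
            intercept_sd=obj["intercept_sd"],
            slope_sd=obj["slope_sd"],
            draws=np.asarray(obj["draws"], dtype=float),
        )

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "RescalingFunction":
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        return cls(
            intercept=float(draws[:, 0].mean()),
            slope=float(draws[:, 1].mean()),
            intercept_sd=float(draws[:, 0].std(ddof=0)),
            slope_sd=float(draws[:, 1].std(ddof=0)),
            draws=draws,
        )


@dataclass
class ErrorModel:
    """Components pooled into the per-pixel assignment SD.

    sigma_ind : permil, between-individual feather SD
    precip : precipitation d2H grid (needed to evaluate the calibration
        variance per pixel from the stored replicate coefficients)
    isoscape_sd : per-pixel SD of the precipitation isoscape
    """

    sigma_ind: float
    precip: IsotopeGrid
    isoscape_sd: IsotopeGrid

    def __post_init__(self) -> None:
        if self.sigma_ind < 0:
            raise ValueError("sigma_ind must be >= 0")
        if not self.precip.aligned_with(self.isoscape_sd):
            raise ValueError("precipitation and SD grids are misaligned")


# ---------------------------------------------------------------------------
# calibration-site table


def load_calibration_sites() -> list[SiteSummary]:
    """The packaged 51-site calibration table (site-level d2H summaries).

    Feather means/SDs are per-site summaries of known-origin birds;
    precipitation means/SDs are growing-season isoscape predictions at the
    sites. One single-bird site has no SDs.
    """
    import csv

    ref = importlib.resources.files("moltrace") / "data" / "calibration_sites.csv"
    sites: list[SiteSummary] = []
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sites.append(
                SiteSummary(
                    site_id=row["site_id"],
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    n=int(row["n"]),
                    f_mean=float(row["f_mean"]),
                    f_sd=float(row["f_sd"]) if row["f_sd"] else None,
                    p_mean=float(row["p_mean"]),
                    p_sd=float(row["p_sd"]) if row["p_sd"] else None,
                )
            )
    return sites


def screen_calibration_sites(
    sites: list[SiteSummary], mad_cutoff: float = 3.5
) -> tuple[list[SiteSummary], list[SiteSummary]]:
    """Split sites into (consistent, flagged) by internal consistency.

    Precipitation d2H over a continental window is dominated by a smooth
    latitude/longitude trend, so a site whose tabulated precipitation value
    departs grossly from the trend fitted to all sites is almost certainly a
    transcription error. Sites are flagged when the absolute residual from
    an OLS fit of p_mean on (lat, lon) exceeds ``mad_cutoff`` robust SDs
    (1.4826 * MAD). Nothing is altered: callers decide what to do with the
    flagged rows.
    """
    lat = np.array([s.lat for s in sites])
    lon = np.array([s.lon for s in sites])
    p = np.array([s.p_mean for s in sites])
    X = np.column_stack([np.ones(len(sites)), lat, lon])
    beta, *_ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ beta
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    scale = 1.4826 * mad if mad > 0 else np.std(resid)
    if scale == 0:
        return list(sites), []
    keep = np.abs(resid - med) <= mad_cutoff * scale
    return (
        [s for s, k in zip(sites, keep) if k],
        [s for s, k in zip(sites, keep) if not k],
    )


# ---------------------------------------------------------------------------
# bootstrap regression


def fit_rescaling_bootstrap(
    sites: list[SiteSummary],
    n_boot: int = 1000,
    seed: int | None = 0,
    *,
    site_mean_se: bool = True,
    per_bird: bool = False,
    missing_sd: str = "impute_mean",
    max_redraws: int = 100,
) -> RescalingFunction:
    """Bootstrap regression of site feather d2H means on precipitation d2H.

    Per replicate, each site contributes a simulated feather mean drawn
    around ``f_mean`` and a precipitation value drawn ~ N(p_mean, p_sd);
    OLS of feather on precipitation across sites is stored. The reported
    coefficients are the means of the replicate draws and the reported SDs
    their spread.

    site_mean_se
        Draw the feather mean with its standard error ``f_sd/sqrt(n)``
        (default). With ``False`` the full ``f_sd`` is used.
    per_bird
        Instead draw ``n`` individual birds ~ N(f_mean, f_sd) and average
        them (an equivalent error model, provided for comparison).
    missing_sd
        "impute_mean" replaces absent SDs by the mean SD of the remaining
        sites; "drop" excludes those sites.
    """
    if missing_sd not in {"impute_mean", "drop"}:
        raise ValueError("missing_sd must be 'impute_mean' or 'drop'")
    usable = [s for s in sites if np.isfinite(s.f_mean) and np.isfinite(s.p_mean)]
    if missing_sd == "drop":
        usable = [s for s in usable if s.f_sd is not None and s.p_sd is not None]
    if len(usable) < 3:
        raise ValueError("need at least 3 usable calibration sites")

    f_sds = np.array([s.f_sd for s in usable if s.f_sd is not None], dtype=float)
    p_sds = np.array([s.p_sd for s in usable if s.p_sd is not None], dtype=float)
    f_sd_fill = float(f_sds.mean()) if f_sds.size else 0.0
    p_sd_fill = float(p_sds.mean()) if p_sds.size else 0.0

    f_mean = np.array([s.f_mean for s in usable])
    p_mean = np.array([s.p_mean for s in usable])
    n = np.array([s.n for s in usable], dtype=float)
    f_sd = np.array([s.f_sd if s.f_sd is not None else f_sd_fill for s in usable])
    p_sd = np.array([s.p_sd if s.p_sd is not None else p_sd_fill for s in usable])

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 2))
    X = np.empty((len(usable), 2))
    X[:, 0] = 1.0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            if per_bird:
                f_draw = np.array(
                    [rng.normal(m, s, size=int(k)).mean() for m, s, k in zip(f_mean, f_sd, n)]
                )
            else:
                scale = f_sd / np.sqrt(n) if site_mean_se else f_sd
                f_draw = rng.normal(f_mean, scale)
            p_draw = rng.normal(p_mean, p_sd)
            if np.ptp(p_draw) > 1e-9:
                break
        else:
            raise RuntimeError("simulated predictor degenerate after bounded redraws")
        X[:, 1] = p_draw
        coeff, *_ = np.linalg.lstsq(X, f_draw, rcond=None)
        draws[b] = coeff
    return RescalingFunction.from_draws(draws)


def apply_rescaling(precip: IsotopeGrid, rf: RescalingFunction) -> IsotopeGrid:
    """Map a precipitation isoscape into feather space; nodata preserved."""
    return precip.copy_with(rf.intercept + rf.slope * precip.values)


def pooled_error_surface(em: ErrorModel, rf: RescalingFunction) -> IsotopeGrid:
    """Per-pixel pooled SD for likelihood assignment.

    pooled^2 = sigma_ind^2 + (slope * isoscape_sd)^2 + Var_b[a_b + b_b * p]
    with the last term the variance across stored calibration replicates of
    the prediction at the pixel's precipitation value. Each term is the
    variance of an independent additive error under the model, so the total
    is a sum in quadrature and never falls below sigma_ind.
    """
    p = em.precip.values
    a = rf.draws[:, 0]
    b = rf.draws[:, 1]
    # Var(a + b p) = Var(a) + p^2 Var(b) + 2 p Cov(a, b), evaluated per pixel
    var_a = a.var(ddof=0)
    var_b = b.var(ddof=0)
    cov_ab = np.mean((a - a.mean()) * (b - b.mean()))
    var_calib = var_a + p**2 * var_b + 2 * p * cov_ab
    pooled = np.sqrt(
        em.sigma_ind**2 + (rf.slope * em.isoscape_sd.values) ** 2 + np.maximum(var_calib, 0.0)
    )
    return em.precip.copy_with(pooled)


# ---------------------------------------------------------------------------
# helpers


def site_summaries_from_samples(
    samples: list[FeatherSample],
    precip: IsotopeGrid,
    precip_sd: IsotopeGrid | None = None,
) -> list[SiteSummary]:
    """Aggregate per-bird feather d2H into SiteSummary rows.

    Precipitation means (and SDs, when a SD grid is given) are read from
    the grids at each site.
    """
    by_site: dict[str, list[FeatherSample]] = {}
    for s in samples:
        by_site.setdefault(s.site_id, []).append(s)
    out: list[SiteSummary] = []
    for site_id, group in by_site.items():
        lat = float(np.mean([g.lat for g in group]))
        lon = float(np.mean([g.lon for g in group]))
        d2h = np.array([g.d2h for g in group])
        r, c = precip.index_of(lat, lon)
        p_mean = float(precip.values[r, c])
        p_sd = float(precip_sd.values[r, c]) if precip_sd is not None else None
        out.append(
            SiteSummary(
                site_id=site_id,
                lat=lat,
                lon=lon,
                n=len(group),
                f_mean=float(d2h.mean()),
                f_sd=float(d2h.std(ddof=1)) if len(group) > 1 else None,
                p_mean=p_mean,
                p_sd=p_sd,
            )
        )
    return out
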