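"""Synthetic study-system generator.

Emulates the statistical structure the downstream analysis assumes for a
continental blackbird study: a smooth growing-season precipitation d2H
surface declining to the north-west (about -20 permil in the south-east of
the study window to about -100 permil in the north-west), feather d2H
linearly rescaled from precipitation d2H with between-individual scatter,
feather d13C as a two-endpoint C3/C4 diet mixture, and feather d15N
centred near 10 permil with an optional arid-region elevation.

Every generator is deterministic under the config seed; independent
substreams are derived per generator so adding one stage never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geo import pairwise_km
from .raster_io import FeatherSample, IsotopeGrid

__all__ = ["SimulationConfig", "SimSite", "make_precip_isoscape", "sample_sites",
           "simulate_feathers", "simulate_crop_covariates"]

KM_PER_DEG_LAT = 111.2


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system (defaults mirror the real study).

    The precipitation surface is ``base + g_lat*(lat-lat0) + g_lon*(lon-lon0)``
    plus a smooth random field; the calibration maps it into feather space as
    ``d2h_f = calib_intercept + calib_slope * d2h_p`` with per-bird scatter
    ``sigma_ind``. Diet d13C mixes a C3 and a C4 endpoint with individual C4
    fractions drawn from a Beta distribution.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (29.5, 48.6, -109.1, -89.6)  # lat_min, lat_max, lon_min, lon_max
    grid_shape: tuple[int, int] = (100, 120)  # rows (lat), cols (lon)
    base_d2h_p: float = -60.5          # permil at the extent centre
    gradient_lat: float = -2.4         # permil per degree latitude (northward)
    gradient_lon: float = 1.8          # permil per degree longitude (eastward)
    noise_sd: float = 3.0              # permil, spatially correlated field
    noise_range_km: float = 300.0      # correlation range of that field
    isoscape_sd_range: tuple[float, float] = (8.9, 11.3)  # per-pixel SD band
    calib_intercept: float = -37.45    # permil (a in d2h_f = a + b*d2h_p)
    calib_slope: float = 0.86          # dimensionless
    sigma_ind: float = 8.4             # permil between-individual feather SD
    c3_endpoint: float = -27.0         # permil feather d13C of a pure C3 diet
    c4_endpoint: float = -12.0         # permil feather d13C of a pure C4 diet
    diet_alpha: float = 2.0            # Beta(alpha, beta) individual C4 fraction
    diet_beta: float = 2.0
    d13c_resid_sd: float = 1.0         # permil
    d15n_mean: float = 10.0            # permil
    d15n_sd: float = 1.7               # permil
    arid_shift: float = 2.0            # permil d15N elevation at arid sites
    crop_total: float = 0.5            # planted fraction of each county
    crop_base: float = 0.5             # C4 weight at the extent centre
    crop_lon_slope: float = 0.02       # C4-weight change per degree longitude
    crop_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.extent
        if not (lat_max > lat_min and lon_max > lon_min):
            raise ValueError("degenerate extent")
        if self.calib_slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if abs(self.c4_endpoint - self.c3_endpoint) < 5:
            raise ValueError("diet endpoints must differ by at least 5 permil")
        for name in ("noise_sd", "sigma_ind", "d13c_resid_sd", "d15n_sd", "crop_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


@dataclass(frozen=True)
class SimSite:
    site_id: str
    lat: float
    lon: float
    state: str = "SIM"
    season: str = "spring"
    arid: bool = False


def _correlated_field(shape: tuple[int, int], cell_km: float, range_km: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Smooth unit-variance field via convolution of white noise.

    Approximates an exponential-covariance field: white noise is convolved
    with an exp(-3 d / range) kernel and restandardised. Only smoothness and
    a controllable correlation length are required downstream.
    """
    white = rng.standard_normal(shape)
    if range_km <= 0 or cell_km <= 0:
        return white
    half = max(1, int(np.ceil(range_km / cell_km)))
    offsets = np.arange(-half, half + 1) * cell_km
    dist = np.hypot(offsets[:, None], offsets[None, :])
    kernel = np.exp(-3.0 * dist / range_km)
    smooth = ndimage.convolve(white, kernel, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_precip_isoscape(config: SimulationConfig) -> tuple[IsotopeGrid, IsotopeGrid]:
    """Synthetic precipitation d2H surface plus its per-pixel SD grid."""
    lat_min, lat_max, lon_min, lon_max = config.extent
    nrows, ncols = config.grid_shape
    cell = max((lat_max - lat_min) / nrows, (lon_max - lon_min) / ncols)
    grid0 = IsotopeGrid(np.zeros((nrows, ncols)), origin_lon=lon_min, origin_lat=lat_max, cell_size=cell)
    lats, lons = grid0.cell_centers()
    lat0, lon0 = (lat_min + lat_max) / 2, (lon_min + lon_max) / 2
    plane = (
        config.base_d2h_p
        + config.gradient_lat * (lats[:, None] - lat0)
        + config.gradient_lon * (lons[None, :] - lon0)
    )
    rng = config.rng(1)
    cell_km = cell * KM_PER_DEG_LAT
    noise = config.noise_sd * _correlated_field((nrows, ncols), cell_km, config.noise_range_km, rng)
    values = plane + noise
    lo, hi = config.isoscape_sd_range
    sd_values = rng.uniform(lo, hi, size=(nrows, ncols))
    return grid0.copy_with(values), grid0.copy_with(sd_values)


def sample_sites(
    config: SimulationConfig,
    n_sites: int,
    min_separation_km: float = 5.0,
    max_tries: int = 10_000,
) -> list[SimSite]:
    """Uniform random sites in the extent with a minimum pairwise spacing."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lat_min, lat_max, lon_min, lon_max = config.extent
    rng = config.rng(2)
    lats: list[float] = []
    lons: list[float] = []
    tries = 0
    while len(lats) < n_sites:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_sites} sites >= {min_separation_km} km apart in {tries} tries"
            )
        tries += 1
        lat = rng.uniform(lat_min, lat_max)
        lon = rng.uniform(lon_min, lon_max)
        if lats:
            d = pairwise_km(np.r_[lats, lat], np.r_[lons, lon])[-1, :-1]
            if d.min() < min_separation_km:
                continue
        lats.append(lat)
        lons.append(lon)
    return [
        SimSite(site_id=f"S{k + 1:03d}", lat=lats[k], lon=lons[k])
        for k in range(n_sites)
    ]


def simulate_feathers(
    config: SimulationConfig,
    sites: list[SimSite],
    n_per_site: int,
    precip: IsotopeGrid | None = None,
) -> list[FeatherSample]:
    """Per-bird feather isotope values under the generative model.

    d2h   = calib_intercept + calib_slope * d2h_p(site) + N(0, sigma_ind)
    d13c  = p*C4 + (1-p)*C3 + N(0, resid),  p ~ Beta(alpha, beta) per bird
    d15n  = N(d15n_mean, d15n_sd) (+ arid_shift at arid-flagged sites)
    """
    if precip is None:
        precip, _ = make_precip_isoscape(config)
    rng = config.rng(3)
    samples: list[FeatherSample] = []
    for site in sites:
        try:
            r, c = precip.index_of(site.lat, site.lon)
        except IndexError as exc:
            raise ValueError(f"site {site.site_id} outside precipitation grid") from exc
        d2h_p = precip.values[r, c]
        if not np.isfinite(d2h_p):
            raise ValueError(f"site {site.site_id} falls in a nodata cell")
        mu_f = config.calib_intercept + config.calib_slope * d2h_p
        d2h = mu_f + rng.normal(0.0, config.sigma_ind, size=n_per_site)
        p_c4 = rng.beta(config.diet_alpha, config.diet_beta, size=n_per_site)
        d13c = (
            p_c4 * config.c4_endpoint
            + (1 - p_c4) * config.c3_endpoint
            + rng.normal(0.0, config.d13c_resid_sd, size=n_per_site)
        )
        d15n = rng.normal(config.d15n_mean, config.d15n_sd, size=n_per_site)
        if site.arid:
            d15n = d15n + config.arid_shift
        for j in range(n_per_site):
            samples.append(
                FeatherSample(
                    bird_id=f"{site.site_id}-B{j + 1:03d}",
                    site_id=site.site_id,
                    lat=site.lat,
                    lon=site.lon,
                    state=site.state,
                    season=site.season,
                    d2h=float(np.clip(d2h[j], -200.0, 0.0)),
                    d13c=float(np.clip(d13c[j], -40.0, 0.0)),
                    d15n=float(np.clip(d15n[j], -5.0, 25.0)),
                )
            )
    return samples


def simulate_crop_covariates(
    sites: list[SimSite], config: SimulationConfig
) -> dict[str, tuple[float, float]]:
    """Per-site (prop_C3, prop_C4) planted-crop proportions.

    A fixed total planted fraction is split between C4 and C3 by a weight
    that drifts linearly with longitude (plus noise), so the C4 share is
    spatially smooth and correlated with longitude with the configured sign.
    """
    rng = config.rng(4)
    lat_min, lat_max, lon_min, lon_max = config.extent
    lon0 = (lon_min + lon_max) / 2
    out: dict[str, tuple[float, float]] = {}
    for site in sites:
        w = config.crop_base + config.crop_lon_slope * (site.lon - lon0)
        w = float(np.clip(w + rng.normal(0.0, config.crop_noise_sd), 0.0, 1.0))
        prop_c4 = config.crop_total * w
        prop_c3 = config.crop_total * (1.0 - w)
        out[site.site_id] = (prop_c3, prop_c4)
    return out
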