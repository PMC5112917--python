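"""Georeferenced isotope grids and tabular feather data.

The package works on simple north-up, square-celled grids in geographic
WGS84 coordinates. A grid carries per-cell isotope values in permil on the
conventional delta scales (VSMOW-SLAP for hydrogen, VPDB for carbon, AIR
for nitrogen); no unit conversion is ever applied. Grids are the carrier
for isoscapes, per-pixel error surfaces, per-bird posterior surfaces and
origin-count maps.

Supported on-disk formats are ESRI ASCII grids (text) and single- or
two-band GeoTIFF (value band + optional SD band), the two formats commonly
exchanged in isoscape work.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IsotopeGrid",
    "FeatherSample",
    "SiteSummary",
    "SchemaError",
    "RowIssue",
    "read_feather_table",
    "read_grid",
    "write_grid",
    "extract_at_points",
]

ISOTOPE_RANGES = {
    "d2h": (-200.0, 0.0),
    "d13c": (-40.0, 0.0),
    "d15n": (-5.0, 25.0),
}

_GRID_VALUE_RANGE = (-500.0, 500.0)


class SchemaError(ValueError):
    """A required column is missing or the file header is malformed."""


@dataclass(frozen=True)
class RowIssue:
    """A row that failed validation; reported, never silently dropped."""

    row: int  # 1-based data-row number (header excluded)
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} [{self.field}]: {self.message}"


@dataclass(frozen=True)
class FeatherSample:
    """One bird: collection metadata plus feather isotope values (permil)."""

    bird_id: str
    site_id: str
    lat: float
    lon: float
    state: str
    season: str  # "spring" | "winter"
    d2h: float
    d13c: float | None = None
    d15n: float | None = None


@dataclass(frozen=True)
class SiteSummary:
    """Site-level calibration row: feather and precipitation d2H summaries."""

    site_id: str
    lat: float
    lon: float
    n: int
    f_mean: float
    f_sd: float | None
    p_mean: float
    p_sd: float | None


@dataclass
class IsotopeGrid:
    """A north-up regular grid of isotope values in geographic WGS84.

    ``values`` is a 2-D float array (rows run north to south); nodata cells
    are held as NaN in memory and written with the ``nodata`` sentinel.
    ``origin_lon``/``origin_lat`` locate the *outer corner* of the
    upper-left cell; ``cell_size`` is degrees per (square) cell.
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata: float = -9999.0
    crs_note: str = "geographic WGS84"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        # sentinel cells -> NaN in memory
        self.values = np.where(self.values == self.nodata, np.nan, self.values)
        finite = self.values[np.isfinite(self.values)]
        lo, hi = _GRID_VALUE_RANGE
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"isotope values outside physical range {lo}..{hi} permil")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of the outer grid edges."""
        nrows, ncols = self.shape
        return (
            self.origin_lat - nrows * self.cell_size,
            self.origin_lat,
            self.origin_lon,
            self.origin_lon + ncols * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lats, lons) 1-D arrays of row / column cell-center coordinates."""
        nrows, ncols = self.shape
        lats = self.origin_lat - (np.arange(nrows) + 0.5) * self.cell_size
        lons = self.origin_lon + (np.arange(ncols) + 0.5) * self.cell_size
        return lats, lons

    def index_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        lat_min, lat_max, lon_min, lon_max = self.extent
        if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
            raise IndexError(f"point ({lat}, {lon}) outside grid extent")
        row = int((self.origin_lat - lat) / self.cell_size)
        col = int((lon - self.origin_lon) / self.cell_size)
        nrows, ncols = self.shape
        return min(row, nrows - 1), min(col, ncols - 1)

    def aligned_with(self, other: "IsotopeGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def copy_with(self, values: np.ndarray) -> "IsotopeGrid":
        return replace(self, values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# tabular I/O


_REQUIRED_COLUMNS = ("bird_id", "lat", "lon", "state", "season", "d2h")


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if text == "" or text.upper() in {"NA", "NAN"}:
        return None
    return float(text)


def read_feather_table(
    path: str | Path, *, errors: str = "raise"
) -> list[FeatherSample] | tuple[list[FeatherSample], list[RowIssue]]:
    """Read a per-bird feather isotope CSV.

    Required columns: bird_id, lat, lon, state, season, d2h (site_id, d13c,
    d15n optional). With ``errors="raise"`` any invalid row aborts with a
    message naming the offending rows; with ``errors="collect"`` the valid
    samples and the list of :class:`RowIssue` are both returned.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column: {col!r}")
        samples: list[FeatherSample] = []
        issues: list[RowIssue] = []
        for i, row in enumerate(reader, start=1):
            sample, row_issues = _parse_row(i, row)
            if row_issues:
                issues.extend(row_issues)
            elif sample is not None:
                samples.append(sample)
    if errors == "collect":
        return samples, issues
    if issues:
        msg = "; ".join(str(x) for x in issues[:10])
        more = f" (+{len(issues) - 10} more)" if len(issues) > 10 else ""
        raise ValueError(f"invalid rows in {path.name}: {msg}{more}")
    return samples


def _parse_row(i: int, row: dict) -> tuple[FeatherSample | None, list[RowIssue]]:
    issues: list[RowIssue] = []

    def num(fieldname: str, required: bool) -> float | None:
        try:
            value = _parse_float(row.get(fieldname) or "")
        except ValueError:
            issues.append(RowIssue(i, fieldname, f"unparseable number {row.get(fieldname)!r}"))
            return None
        if value is None and required:
            issues.append(RowIssue(i, fieldname, "missing required value"))
        return value

    lat = num("lat", True)
    lon = num("lon", True)
    d2h = num("d2h", True)
    d13c = num("d13c", False) if "d13c" in row else None
    d15n = num("d15n", False) if "d15n" in row else None
    season = (row.get("season") or "").strip().lower()
    if season not in {"spring", "winter"}:
        issues.append(RowIssue(i, "season", f"must be spring or winter, got {season!r}"))
    if lat is not None and not -90 <= lat <= 90:
        issues.append(RowIssue(i, "lat", f"latitude {lat} outside [-90, 90]"))
    if lon is not None and not -180 <= lon <= 180:
        issues.append(RowIssue(i, "lon", f"longitude {lon} outside [-180, 180]"))
    for name, value in (("d2h", d2h), ("d13c", d13c), ("d15n", d15n)):
        lo, hi = ISOTOPE_RANGES[name]
        if value is not None and not lo <= value <= hi:
            issues.append(RowIssue(i, name, f"{value} permil outside [{lo}, {hi}]"))
    if issues:
        return None, issues
    return (
        FeatherSample(
            bird_id=str(row.get("bird_id", "")).strip(),
            site_id=str(row.get("site_id", "") or "").strip(),
            lat=float(lat),
            lon=float(lon),
            state=(row.get("state") or "").strip(),
            season=season,
            d2h=float(d2h),
            d13c=d13c,
            d15n=d15n,
        ),
        [],
    )


# ---------------------------------------------------------------------------
# raster I/O

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        return "esri_ascii"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer raster format from {path.name!r}; pass format=")


def write_grid(
    grid: IsotopeGrid,
    path: str | Path,
    format: str | None = None,
    sd_grid: IsotopeGrid | None = None,
) -> None:
    """Write a grid (ESRI ASCII or GeoTIFF); SD grid becomes band 2 (GeoTIFF only)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "esri_ascii":
        if sd_grid is not None:
            raise ValueError("ESRI ASCII supports a single band; write the SD grid separately")
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path, sd_grid)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None, band: int = 1) -> IsotopeGrid:
    """Read a grid; ``band=2`` selects the SD band of a two-band GeoTIFF."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "esri_ascii":
        if band != 1:
            raise ValueError("ESRI ASCII grids are single-band")
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path, band)
    raise ValueError(f"unknown raster format {fmt!r}")


def _write_ascii(grid: IsotopeGrid, path: Path) -> None:
    nrows, ncols = grid.shape
    yllcorner = grid.origin_lat - nrows * grid.cell_size
    out = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(grid.origin_lon)!r}\n")
        fh.write(f"yllcorner {float(yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for r in range(nrows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def _read_ascii(path: Path) -> IsotopeGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key}")
    values = np.array(rows, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    return IsotopeGrid(
        values=values,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )


def _write_geotiff(grid: IsotopeGrid, path: Path, sd_grid: IsotopeGrid | None) -> None:
    import tifffile

    bands = [grid.values]
    if sd_grid is not None:
        if not grid.aligned_with(sd_grid):
            raise ValueError("SD grid not aligned with value grid")
        bands.append(sd_grid.values)
    data = np.stack(
        [np.where(np.isfinite(b), b, grid.nodata) for b in bands]
    ).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def _read_geotiff(path: Path, band: int) -> IsotopeGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path.name}: not a GeoTIFF (no georeferencing tags)")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-12:
            raise ValueError("unsupported geometry: non-square cells")
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else -9999.0
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if band < 1 or band > data.shape[0]:
        raise ValueError(f"band {band} not present (file has {data.shape[0]})")
    return IsotopeGrid(
        values=data[band - 1].astype(float),
        origin_lon=float(tie[3]),
        origin_lat=float(tie[4]),
        cell_size=float(sx),
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# point extraction


def extract_at_points(
    grid: IsotopeGrid,
    points: Sequence[tuple[float, float]],
    method: str = "nearest",
) -> tuple[np.ndarray, list[str]]:
    """Read grid values at (lat, lon) points.

    Returns (values, flags); flags are "ok", "nodata" or "outside". The
    default rule is nearest-cell (the value of the cell containing the
    point); ``method="bilinear"`` interpolates between cell centers.
    """
    if method not in {"nearest", "bilinear"}:
        raise ValueError("method must be 'nearest' or 'bilinear'")
    values = np.full(len(points), np.nan)
    flags: list[str] = []
    for k, (lat, lon) in enumerate(points):
        try:
            r, c = grid.index_of(lat, lon)
        except IndexError:
            flags.append("outside")
            continue
        if method == "nearest":
            v = grid.values[r, c]
        else:
            v = _bilinear(grid, lat, lon)
        if np.isfinite(v):
            values[k] = v
            flags.append("ok")
        else:
            flags.append("nodata")
    return values, flags


def _bilinear(grid: IsotopeGrid, lat: float, lon: float) -> float:
    lats, lons = grid.cell_centers()
    # fractional index into cell-center space (clamped to the border)
    fy = np.clip((lats[0] - lat) / grid.cell_size, 0, len(lats) - 1)
    fx = np.clip((lon - lons[0]) / grid.cell_size, 0, len(lons) - 1)
    r0, c0 = int(math.floor(fy)), int(math.floor(fx))
    r1, c1 = min(r0 + 1, len(lats) - 1), min(c0 + 1, len(lons) - 1)
    wy, wx = fy - r0, fx - c0
    z = grid.values
    corners = np.array([z[r0, c0], z[r0, c1], z[r1, c0], z[r1, c1]])
    weights = np.array([(1 - wy) * (1 - wx), (1 - wy) * wx, wy * (1 - wx), wy * wx])
    if not np.all(np.isfinite(corners[weights > 0])):
        return np.nan
    mask = weights > 0
    return float(np.sum(corners[mask] * weights[mask]))
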