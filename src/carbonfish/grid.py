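"""Grid geometry, spherical cell areas, regridding and global integration.

Everything downstream works on a regular latitude-longitude grid that is
cell-edge registered: latitude edges ascend from -90 to 90, longitude edges
from -180 to 180, with a uniform resolution in degrees. Cell membership is
half-open ``[edge_low, edge_high)`` with the final edge closed, so every
point maps to exactly one cell.

Cell areas use the exact spherical closed form

    A = R^2 * dlambda * (sin(phi2) - sin(phi1))

with R = 6371 km by default, which conserves the sphere surface exactly
(up to floating point) on any uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: canonical unit strings used in field metadata
UNITS_EXPORT = "mg C m-2 day-1"
UNITS_FISHING = "h km-2 yr-1"
UNITS_SST = "degC"
UNITS_NPP = "mg C m-2 day-1"
UNITS_DEPTH = "m"

#: mg -> Gt conversion (1 Gt = 1e15 g = 1e18 mg)
_MG_PER_GT = 1e18
_M2_PER_KM2 = 1e6
_DAYS_PER_YEAR = 365.0


class GridError(ValueError):
    """Raised for malformed or incompatible grid geometry."""


@dataclass(frozen=True)
class GeoGrid:
    """A uniform global latitude-longitude grid, edge registered.

    Parameters
    ----------
    lat_edges, lon_edges:
        Strictly increasing cell-edge vectors in degrees, covering
        -90..90 and -180..180 respectively, with uniform spacing.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_edges, dtype=float)
        lon = np.asarray(self.lon_edges, dtype=float)
        object.__setattr__(self, "lat_edges", lat)
        object.__setattr__(self, "lon_edges", lon)
        for name, edges in (("lat", lat), ("lon", lon)):
            if edges.ndim != 1 or edges.size < 2:
                raise GridError(f"{name}_edges must be a 1-d vector of >=2 edges")
            steps = np.diff(edges)
            if np.any(steps <= 0):
                raise GridError(f"{name}_edges must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise GridError(f"{name}_edges must be uniformly spaced")
        if not (np.isclose(lat[0], -90.0) and np.isclose(lat[-1], 90.0)):
            raise GridError("lat_edges must span -90..90")
        if not (np.isclose(lon[0], -180.0) and np.isclose(lon[-1], 180.0)):
            raise GridError("lon_edges must span -180..180")

    @classmethod
    def regular(cls, resolution: float) -> "GeoGrid":
        """Build a global grid with the given resolution in degrees."""
        n_lat = round(180.0 / resolution)
        n_lon = round(360.0 / resolution)
        if not (np.isclose(n_lat * resolution, 180.0) and np.isclose(n_lon * resolution, 360.0)):
            raise GridError(f"resolution {resolution} does not tile the globe")
        return cls(
            lat_edges=np.linspace(-90.0, 90.0, n_lat + 1),
            lon_edges=np.linspace(-180.0, 180.0, n_lon + 1),
        )

    @property
    def resolution(self) -> float:
        return float(self.lat_edges[1] - self.lat_edges[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_edges.size - 1, self.lon_edges.size - 1)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeoGrid):
            return NotImplemented
        return (
            self.lat_edges.shape == other.lat_edges.shape
            and self.lon_edges.shape == other.lon_edges.shape
            and np.allclose(self.lat_edges, other.lat_edges)
            and np.allclose(self.lon_edges, other.lon_edges)
        )


@dataclass
class GriddedField:
    """One gridded variable with a validity mask and a unit string.

    ``values`` must be finite wherever ``valid`` is True; invalid cells may
    hold anything (they are never read).
    """

    grid: GeoGrid
    values: np.ndarray
    valid: np.ndarray | None = None
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise GridError("valid mask shape does not match grid")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise GridError("non-finite values inside the validity mask")

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN (for plotting / export)."""
        out = np.where(self.valid, self.values, np.nan)
        return out

    def with_values(self, values: np.ndarray, units: str | None = None,
                    name: str | None = None) -> "GriddedField":
        return GriddedField(
            grid=self.grid,
            values=values,
            valid=self.valid.copy(),
            units=self.units if units is None else units,
            name=self.name if name is None else name,
        )


@dataclass(frozen=True)
class CellAreas:
    """Spherical surface area of every cell, km^2."""

    grid: GeoGrid
    area: np.ndarray
    sphere_radius: float = EARTH_RADIUS_KM


def cell_areas(grid: GeoGrid, radius: float = EARTH_RADIUS_KM) -> CellAreas:
    """Exact spherical cell areas for a uniform lat-lon grid.

    The band area R^2 * dlambda * (sin(phi2) - sin(phi1)) telescopes over
    latitude, so the total equals 4*pi*R^2 up to rounding.
    """
    phi = np.deg2rad(grid.lat_edges)
    dlam = np.deg2rad(np.diff(grid.lon_edges))
    band = radius**2 * (np.sin(phi[1:]) - np.sin(phi[:-1]))  # per unit radian
    area = band[:, None] * dlam[None, :]
    return CellAreas(grid=grid, area=area, sphere_radius=radius)


def regrid_mean(field: GriddedField, target: GeoGrid,
                areas: CellAreas | None = None) -> GriddedField:
    """Area-weighted mean regridding onto an exactly nesting coarser grid.

    Only intensive (per-area) variables may be regridded this way. The
    target resolution must be an integer multiple of the source resolution;
    no interpolation is ever attempted. A target cell is invalid iff all
    source cells inside it are invalid.
    """
    src = field.grid
    factor = target.resolution / src.resolution
    k = round(factor)
    if k < 1 or not np.isclose(factor, k, rtol=0, atol=1e-9):
        raise GridError(
            f"target resolution {target.resolution} is not an integer multiple "
            f"of source resolution {src.resolution}"
        )
    if src.shape[0] != k * target.shape[0] or src.shape[1] != k * target.shape[1]:
        raise GridError("source grid does not nest into target grid")
    if areas is None:
        areas = cell_areas(src)
    elif areas.grid != src:
        raise GridError("areas computed on a different grid than the field")

    n_lat, n_lon = target.shape
    # zero out invalid cells so NaN payloads never contaminate the sums
    v = np.where(field.valid, field.values, 0.0).reshape(n_lat, k, n_lon, k)
    a = areas.area.reshape(n_lat, k, n_lon, k)
    m = field.valid.reshape(n_lat, k, n_lon, k)

    w = a * m
    wsum = w.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        out = (v * w).sum(axis=(1, 3)) / wsum
    valid = wsum > 0
    out = np.where(valid, out, np.nan)
    return GriddedField(grid=target, values=out, valid=valid,
                        units=field.units, name=field.name)


def log_z(field: GriddedField) -> GriddedField:
    """z-score of log(value + eps) over valid cells, for visualization only.

    eps is the smallest positive valid value times 1e-3, which keeps exact
    zeros finite without distorting the positive tail. A zero-variance log
    field maps to all zeros (constant fields carry no contrast to show).
    """
    if not field.valid.any():
        raise GridError("log_z of an all-invalid field")
    vals = field.values[field.valid]
    if np.any(vals < 0):
        raise GridError("log_z requires non-negative values")
    positive = vals[vals > 0]
    eps = positive.min() * 1e-3 if positive.size else 1e-12
    logged = np.log(field.values + eps, where=field.valid,
                    out=np.zeros_like(field.values))
    mu = logged[field.valid].mean()
    sd = logged[field.valid].std()  # population SD
    if sd <= 1e-12 * (1.0 + abs(mu)):  # zero up to accumulation noise
        z = np.zeros_like(field.values)
    else:
        z = (logged - mu) / sd
    z = np.where(field.valid, z, np.nan)
    return GriddedField(grid=field.grid, values=z, valid=field.valid.copy(),
                        units="z(log)", name=f"log_z({field.name})" if field.name else "log_z")


def global_integral(export: GriddedField, areas: CellAreas,
                    domain: np.ndarray | None = None) -> float:
    """Integrate an export field to Gt C yr^-1.

    ``export`` must be in mg C m^-2 day^-1 (checked against the field's unit
    metadata); the integral is sum(E * area_m2 * 365) / 1e18 over the valid
    cells intersected with ``domain`` if given.
    """
    if export.units and export.units != UNITS_EXPORT:
        raise GridError(
            f"global_integral expects units '{UNITS_EXPORT}', got '{export.units}'"
        )
    if areas.grid != export.grid:
        raise GridError("areas computed on a different grid than the field")
    mask = export.valid if domain is None else (export.valid & np.asarray(domain, bool))
    total_mg_day = float(np.sum(export.values[mask] * areas.area[mask] * _M2_PER_KM2))
    return total_mg_day * _DAYS_PER_YEAR / _MG_PER_GT
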