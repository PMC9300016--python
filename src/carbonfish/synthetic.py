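"""Synthetic gridded worlds with the spatial structure the analysis assumes.

The generator emulates the statistical character of an annual-mean ocean
climatology and a vessel-tracking effort map, without any download:

* positive-valued, spatially autocorrelated fields (log-normal transforms
  of Gaussian random fields, built by convolving seeded white noise with a
  Gaussian kernel at a configurable correlation length);
* a tunable cross-correlation ``rho`` between the export driver (log-NPP)
  and log-fishing — the independent noise is orthogonalized against the
  shared driver over ocean cells, so the realized log-space correlation
  equals ``rho`` exactly, not just in expectation;
* irregular coastlines (land as thresholded smooth noise) with an optional
  multiplicative coastal enhancement of both productivity and fishing
  within one correlation length of land;
* a polar ice/cloud analogue that invalidates the export drivers poleward
  of a configurable latitude while leaving fishing observed;
* a nearest-seed-point partition of the ocean into contiguous regions, and
  Dirichlet-allocated catch tonnage across gear and species-group codes.

Identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .catch import GEAR_CODES, GROUP_CODES
from .export import ExportInputs
from .grid import (GeoGrid, GriddedField, UNITS_DEPTH, UNITS_FISHING,
                   UNITS_NPP, UNITS_SST)
from .regional import RegionMask


class SyntheticError(ValueError):
    """Raised for configs that cannot produce a usable world."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world.

    Defaults describe the study-like conditions: a 2-degree grid, ~29% land,
    19 regions, moderate coupling between productivity and fishing, and a
    doubling of both services along coastlines.
    """

    resolution: float = 2.0
    seed: int = 0
    land_fraction: float = 0.29
    correlation_length: float = 6.0     # degrees
    cross_correlation: float = 0.6      # rho between log-NPP and log-fishing
    coastal_boost: float = 2.0          # multiplicative, within one corr. length of land
    ice_mask_poleward_of: float = 70.0  # degrees latitude
    n_regions: int = 19
    sst_mean: float = 14.0              # degC
    sst_sd: float = 4.0
    sst_lat_amplitude: float = 12.0     # equator-to-pole gradient scale
    npp_log_mean: float = 5.7           # ln(mg C m-2 day-1); e^5.7 ~ 300
    npp_log_sd: float = 0.7
    fishing_log_mean: float = -1.8      # ln(h km-2 yr-1); e^-1.8 ~ 0.17
    fishing_log_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.land_fraction < 1:
            raise SyntheticError("land_fraction must be in [0, 1)")
        if not -1 <= self.cross_correlation <= 1:
            raise SyntheticError("cross_correlation must be in [-1, 1]")
        if self.correlation_length <= 0 or self.resolution <= 0:
            raise SyntheticError("correlation_length and resolution must be positive")
        if self.coastal_boost <= 0:
            raise SyntheticError("coastal_boost must be positive")
        if self.n_regions < 1:
            raise SyntheticError("n_regions must be >= 1")


@dataclass
class SyntheticWorld:
    """Everything gen_fields produces, bundled."""

    config: SyntheticConfig
    grid: GeoGrid
    inputs: ExportInputs          # SST, NPP, Zeu, model_export drivers
    fishing: GriddedField
    land: np.ndarray              # boolean, True = land
    ocean: np.ndarray             # boolean, True = ocean


def _smooth_standard(rng: np.random.Generator, grid: GeoGrid,
                     correlation_length: float) -> np.ndarray:
    """Standardized Gaussian random field with the requested scale.

    White noise convolved with a Gaussian kernel (sigma = correlation
    length in cells, truncated at 3 sigma), periodic in longitude and
    clamped at the poles, then standardized to mean 0 / SD 1 over the grid.
    """
    sigma = correlation_length / grid.resolution
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode=("nearest", "wrap"),
                                     truncate=3.0)
    return (smooth - smooth.mean()) / smooth.std()


def _standardize_on(x: np.ndarray, sel: np.ndarray) -> np.ndarray:
    sd = x[sel].std()
    if sd == 0:
        raise SyntheticError("degenerate (constant) random field")
    return (x - x[sel].mean()) / sd


def gen_fields(config: SyntheticConfig) -> SyntheticWorld:
    """Generate the driver fields, the fishing field and the land mask."""
    rng = np.random.default_rng(config.seed)
    grid = GeoGrid.regular(config.resolution)
    latc = grid.lat_centers[:, None] * np.ones((1, grid.shape[1]))

    # land: thresholded smooth noise -> irregular coastlines at the target fraction
    if config.land_fraction > 0:
        land_noise = _smooth_standard(rng, grid, config.correlation_length)
        land = land_noise > np.quantile(land_noise, 1 - config.land_fraction)
    else:
        _ = rng.standard_normal(grid.shape)  # keep the stream aligned
        land = np.zeros(grid.shape, dtype=bool)
    ocean = ~land
    if not ocean.any():
        raise SyntheticError("land_fraction leaves no ocean")

    # shared driver S and fishing-only noise N, orthogonalized on ocean cells
    s = _standardize_on(_smooth_standard(rng, grid, config.correlation_length), ocean)
    n = _smooth_standard(rng, grid, config.correlation_length)
    beta = np.mean(n[ocean] * s[ocean]) - n[ocean].mean() * s[ocean].mean()
    n_perp = _standardize_on(n - beta * s, ocean)
    rho = config.cross_correlation
    f_z = rho * s + np.sqrt(1 - rho**2) * n_perp

    npp = np.exp(config.npp_log_mean + config.npp_log_sd * s)
    fishing = np.exp(config.fishing_log_mean + config.fishing_log_sd * f_z)

    # coastal enhancement of both services within one correlation length of land
    if config.coastal_boost != 1.0 and land.any():
        dist_deg = ndimage.distance_transform_edt(ocean) * config.resolution
        coastal = ocean & (dist_deg <= config.correlation_length)
        npp = np.where(coastal, npp * config.coastal_boost, npp)
        fishing = np.where(coastal, fishing * config.coastal_boost, fishing)

    sst_noise = _smooth_standard(rng, grid, config.correlation_length)
    cos_lat = np.cos(np.deg2rad(latc))
    sst = (config.sst_mean
           + config.sst_lat_amplitude * (cos_lat - cos_lat.mean())
           + config.sst_sd * sst_noise)
    sst = np.maximum(sst, -2.0)  # seawater freezing point

    # euphotic depth shoals with productivity (clear gyres deep, coasts shallow)
    zeu = np.clip(34.0 * np.power(npp / 1000.0, -0.39), 20.0, 180.0)

    # a synthetic 'model product' export member: fixed ratio times NPP with
    # its own multiplicative error field
    model_noise = _smooth_standard(rng, grid, config.correlation_length)
    model_export = 0.15 * npp * np.exp(0.3 * model_noise)

    ice = np.abs(latc) >= config.ice_mask_poleward_of
    driver_valid = ocean & ~ice          # export retrieval fails under ice/cloud
    fish_valid = ocean                   # vessel tracking sees the whole ocean

    def f(vals, valid, units, name):
        return GriddedField(grid=grid, values=np.where(valid, vals, np.nan),
                            valid=valid, units=units, name=name)

    inputs = ExportInputs(
        sst=f(sst, driver_valid, UNITS_SST, "sst"),
        npp=f(npp, driver_valid, UNITS_NPP, "npp"),
        zeu=f(zeu, driver_valid, UNITS_DEPTH, "zeu"),
        model_export=f(model_export, driver_valid, UNITS_NPP, "model_export"),
    )
    fishing_field = f(fishing, fish_valid, UNITS_FISHING, "fishing")
    return SyntheticWorld(config=config, grid=grid, inputs=inputs,
                          fishing=fishing_field, land=land, ocean=ocean)


def _great_circle(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Central angle between points, radians (haversine)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def gen_regions(grid: GeoGrid, n_regions: int, seed: int,
                ocean: np.ndarray | None = None) -> RegionMask:
    """Partition the ocean into contiguous regions by nearest seed point.

    Seed points are drawn uniformly over ocean cells; each ocean cell joins
    the region of its nearest seed by great-circle distance, so every
    region is non-empty (each seed cell is distance 0 from itself).
    """
    if ocean is None:
        ocean = np.ones(grid.shape, dtype=bool)
    ocean = np.asarray(ocean, dtype=bool)
    idx_lat, idx_lon = np.nonzero(ocean)
    if n_regions < 1 or n_regions > idx_lat.size:
        raise SyntheticError(
            f"n_regions={n_regions} not achievable on {idx_lat.size} ocean cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx_lat.size, size=n_regions, replace=False)
    lat_s = grid.lat_centers[idx_lat[pick]]
    lon_s = grid.lon_centers[idx_lon[pick]]
    lat_c = grid.lat_centers[idx_lat]
    lon_c = grid.lon_centers[idx_lon]
    d = _great_circle(lat_c[:, None], lon_c[:, None],
                      lat_s[None, :], lon_s[None, :])
    assign = np.argmin(d, axis=1) + 1
    region_id = np.zeros(grid.shape, dtype=int)
    region_id[idx_lat, idx_lon] = assign
    codes = {i: f"Region {i:02d}" for i in range(1, n_regions + 1)}
    return RegionMask(grid=grid, region_id=region_id, codes=codes)


def gen_catch(regions: RegionMask, seed: int,
              concentration: float = 1.0) -> pd.DataFrame:
    """Synthetic catch records across the gear and species-group vocabularies.

    Per region, a log-normal total tonnage is allocated over gear x group
    as the outer product of two Dirichlet draws with the given
    concentration: small concentration concentrates the catch in one
    category, large concentration spreads it nearly uniformly.
    """
    if concentration <= 0:
        raise SyntheticError("concentration must be positive")
    region_ids = sorted(regions.codes)
    if not region_ids:
        raise SyntheticError("region mask has no regions")
    rng = np.random.default_rng(seed)
    rows = []
    for rid in region_ids:
        total = rng.lognormal(mean=np.log(1e6), sigma=1.0)
        gear_share = rng.dirichlet(np.full(len(GEAR_CODES), concentration))
        group_share = rng.dirichlet(np.full(len(GROUP_CODES), concentration))
        tonnage = total * np.outer(gear_share, group_share)
        for i, gear in enumerate(GEAR_CODES):
            for j, group in enumerate(GROUP_CODES):
                if tonnage[i, j] > 0:
                    rows.append((rid, gear, group, float(tonnage[i, j])))
    return pd.DataFrame(rows, columns=["region", "gear", "group", "tonnes"])
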