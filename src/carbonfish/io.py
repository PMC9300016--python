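"""Reading and writing gridded fields, region masks and catch tables.

Gridded variables travel as single-variable NetCDF (via xarray, classic
format) with explicit ``lat_edges`` / ``lon_edges`` coordinate variables —
edges are stored alongside centers precisely to avoid center/edge
registration ambiguity — or as a CSV dump with columns
``lat_center, lon_center, value``. Region masks and catch records are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .catch import CATCH_COLUMNS
from .grid import GeoGrid, GriddedField, GridError
from .regional import RegionMask


def _grid_from_centers(lat_c: np.ndarray, lon_c: np.ndarray) -> GeoGrid:
    lat_c = np.asarray(lat_c, float)
    lon_c = np.asarray(lon_c, float)
    res = lat_c[1] - lat_c[0] if lat_c.size > 1 else lon_c[1] - lon_c[0]
    lat_edges = np.concatenate([lat_c - res / 2, [lat_c[-1] + res / 2]])
    lon_edges = np.concatenate([lon_c - res / 2, [lon_c[-1] + res / 2]])
    return GeoGrid(lat_edges=lat_edges, lon_edges=lon_edges)


def field_to_dataset(field: GriddedField) -> xr.Dataset:
    name = field.name or "value"
    ds = xr.Dataset(
        {name: (("lat", "lon"), field.masked())},
        coords={
            "lat": field.grid.lat_centers,
            "lon": field.grid.lon_centers,
            "lat_edges": ("lat_edge", field.grid.lat_edges),
            "lon_edges": ("lon_edge", field.grid.lon_edges),
        },
    )
    ds[name].attrs["units"] = field.units
    ds[name].attrs["long_name"] = name
    return ds


def write_field(path: str | Path, field: GriddedField) -> None:
    path = Path(path)
    if path.suffix == ".nc":
        field_to_dataset(field).to_netcdf(path, engine="scipy")
    elif path.suffix == ".csv":
        lat, lon = np.meshgrid(field.grid.lat_centers, field.grid.lon_centers,
                               indexing="ij")
        pd.DataFrame({
            "lat_center": lat.ravel(),
            "lon_center": lon.ravel(),
            "value": field.masked().ravel(),
        }).to_csv(path, index=False)
    else:
        raise GridError(f"unsupported field format: {path.suffix}")


def read_field(path: str | Path, name: str = "", units: str = "") -> GriddedField:
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            var = name or next(
                v for v in ds.data_vars if ds[v].dims == ("lat", "lon"))
            if "lat_edges" in ds:
                grid = GeoGrid(lat_edges=ds["lat_edges"].values.copy(),
                               lon_edges=ds["lon_edges"].values.copy())
            else:
                grid = _grid_from_centers(ds["lat"].values, ds["lon"].values)
            values = ds[var].values.astype(float)
            units = units or str(ds[var].attrs.get("units", ""))
            varname = str(var)
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        lat_c = np.unique(df["lat_center"])
        lon_c = np.unique(df["lon_center"])
        grid = _grid_from_centers(lat_c, lon_c)
        values = (df.pivot(index="lat_center", columns="lon_center", values="value")
                  .reindex(index=lat_c, columns=lon_c).to_numpy(float))
        varname = name or path.stem
    else:
        raise GridError(f"unsupported field format: {path.suffix}")
    return GriddedField(grid=grid, values=values, valid=np.isfinite(values),
                        units=units, name=name or varname)


def write_region_mask(path: str | Path, mask: RegionMask) -> None:
    lat, lon = np.meshgrid(mask.grid.lat_centers, mask.grid.lon_centers,
                           indexing="ij")
    pd.DataFrame({
        "lat_center": lat.ravel(),
        "lon_center": lon.ravel(),
        "region_id": mask.region_id.ravel(),
    }).to_csv(path, index=False)


def read_region_mask(path: str | Path,
                     codes: dict[int, str] | None = None) -> RegionMask:
    df = pd.read_csv(path)
    lat_c = np.unique(df["lat_center"])
    lon_c = np.unique(df["lon_center"])
    grid = _grid_from_centers(lat_c, lon_c)
    region_id = (df.pivot(index="lat_center", columns="lon_center",
                          values="region_id")
                 .reindex(index=lat_c, columns=lon_c).to_numpy(int))
    if codes is None:
        codes = {int(i): f"Region {int(i):02d}"
                 for i in np.unique(region_id) if i != 0}
    return RegionMask(grid=grid, region_id=region_id, codes=codes)


def read_catch(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CATCH_COLUMNS if c not in df.columns]
    if missing:
        raise GridError(f"catch CSV missing columns: {missing}")
    return df
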