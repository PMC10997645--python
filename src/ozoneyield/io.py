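"""Readers and writers for the pipeline's on-disk formats.

Cubes and rasters travel as NetCDF (classic format, via xarray's scipy
engine) with CF-style (time, lat, lon) layout; region and district polygons
as GeoJSON FeatureCollections with a ``name`` property; tables as CSV;
fitted flux-effect models as YAML.  Coordinates stored are cell centres;
the exact grid spec travels in global attributes (with a centre-coordinate
fallback for files written elsewhere), so write -> read is value-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import mapping, shape

from .dose_response import FluxEffectModel
from .exposure import FluxCube
from .grid import GridSpec, RasterField
from .production import ProductionRaster

__all__ = [
    "write_cube", "read_cube",
    "write_raster", "read_raster", "read_production",
    "write_regions", "read_regions",
    "write_model", "read_model",
    "write_table", "read_table",
]

_ENGINE = "scipy"


def _coords(grid: GridSpec) -> dict:
    return {"lat": grid.lat_centers(), "lon": grid.lon_centers()}


_GRID_ATTRS = ("origin_lon", "origin_lat", "cell_size_lon", "cell_size_lat")


def _grid_attrs(grid: GridSpec) -> dict:
    return {k: float(getattr(grid, k)) for k in _GRID_ATTRS}


def _grid_from_ds(ds) -> GridSpec:
    lat, lon = ds["lat"].values, ds["lon"].values
    if all(k in ds.attrs for k in _GRID_ATTRS):
        return GridSpec(n_cols=len(lon), n_rows=len(lat),
                        **{k: float(ds.attrs[k]) for k in _GRID_ATTRS})
    # fall back to inferring the spec from cell-centre coordinates
    if len(lat) < 2 or len(lon) < 2:
        raise ValueError("need at least 2 coordinates per axis to infer the grid")
    dlat = float(lat[1] - lat[0])
    dlon = float(lon[1] - lon[0])
    return GridSpec(
        origin_lon=float(lon[0]) - dlon / 2.0,
        origin_lat=float(lat[0]) - dlat / 2.0,
        cell_size_lon=dlon,
        cell_size_lat=dlat,
        n_cols=len(lon),
        n_rows=len(lat),
    )


def write_cube(cube: FluxCube, path: str | Path) -> None:
    var = "pod_daily" if cube.mode == "daily" else "flux_hourly"
    da = xr.DataArray(
        cube.values,
        dims=("time", "lat", "lon"),
        coords={"time": cube.time, **_coords(cube.grid)},
        name=var,
        attrs={"units": cube.units},
    )
    ds = da.to_dataset()
    ds.attrs.update(_grid_attrs(cube.grid))
    ds.to_netcdf(path, engine=_ENGINE)


def read_cube(path: str | Path) -> FluxCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    if "pod_daily" in ds:
        var, mode = "pod_daily", "daily"
    elif "flux_hourly" in ds:
        var, mode = "flux_hourly", "hourly"
    else:
        raise ValueError(f"{path}: no pod_daily or flux_hourly variable")
    grid = _grid_from_ds(ds)
    return FluxCube(grid=grid, time=pd.DatetimeIndex(ds["time"].values),
                    values=ds[var].values, mode=mode)


def write_raster(field: RasterField, path: str | Path, name: str = "value",
                 attrs: dict | None = None) -> None:
    if field.is_categorical:
        raise ValueError("categorical rasters are written as integer codes; encode first")
    vals = np.where(field.missing, np.nan, field.values.astype(float))
    da = xr.DataArray(vals, dims=("lat", "lon"), coords=_coords(field.grid),
                      name=name, attrs={"units": field.units, **(attrs or {})})
    ds = da.to_dataset()
    ds.attrs.update(_grid_attrs(field.grid))
    ds.to_netcdf(path, engine=_ENGINE)


def read_raster(path: str | Path, name: str = "value") -> RasterField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    da = ds[name]
    grid = _grid_from_ds(ds)
    return RasterField(grid, da.values, units=str(da.attrs.get("units", "")))


def write_production(raster: ProductionRaster, path: str | Path) -> None:
    attrs = {"season": raster.season}
    if raster.year is not None:
        attrs["year"] = int(raster.year)
    write_raster(raster, path, name="production", attrs=attrs)


def read_production(path: str | Path) -> ProductionRaster:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds = ds.load()
    da = ds["production"]
    grid = _grid_from_ds(ds)
    year = da.attrs.get("year")
    return ProductionRaster(
        grid, da.values, units=str(da.attrs.get("units", "t")),
        year=int(year) if year is not None else None,
        season=str(da.attrs.get("season", "annual")),
    )


def write_regions(polygons: dict, path: str | Path,
                  properties: dict[str, dict] | None = None) -> None:
    features = []
    for name, geom in polygons.items():
        props = {"name": name, **(properties or {}).get(name, {})}
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(geom)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_regions(path: str | Path) -> tuple[dict, dict[str, dict]]:
    """Returns (name -> geometry, name -> remaining properties)."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    polygons, props = {}, {}
    for feat in fc["features"]:
        p = dict(feat.get("properties") or {})
        name = p.pop("name", None)
        if name is None:
            raise ValueError(f"{path}: feature without a 'name' property")
        polygons[name] = shape(feat["geometry"])
        props[name] = p
    return polygons, props


def write_model(model: FluxEffectModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def read_model(path: str | Path) -> FluxEffectModel:
    d = yaml.safe_load(Path(path).read_text())
    d["slope_ci"] = tuple(d.get("slope_ci", (float("nan"),) * 2))
    d["intercept_ci"] = tuple(d.get("intercept_ci", (float("nan"),) * 2))
    return FluxEffectModel(**d)


def write_table(df: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        for line in filter(None, comment.splitlines()):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
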