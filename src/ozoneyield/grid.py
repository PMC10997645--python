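"""Grids, regions and spatial plumbing.

Everything downstream of this module works on rectilinear lon/lat grids in
geographic degrees.  A cell ``(row j, col i)`` owns the half-open box
``[origin_lon + i*dlon, origin_lon + (i+1)*dlon) x
[origin_lat + j*dlat, origin_lat + (j+1)*dlat)``; row 0 is the southernmost
row.  Overlap areas are computed on the planar degree grid — the study domain
sits on the equator, where the distortion of treating degrees as planar is
negligible, and planar areas keep every overlap computation exact and
brute-force checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "RasterField",
    "RegionMap",
    "assign_cells",
    "regrid",
    "zonal_stat",
]

UNASSIGNED = ""


@dataclass(frozen=True)
class GridSpec:
    """Rectilinear lon/lat grid: origin at the south-west corner."""

    origin_lon: float
    origin_lat: float
    cell_size_lon: float
    cell_size_lat: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_lon <= 0 or self.cell_size_lat <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one column and one row")

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) — the shape of any values array on this grid."""
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        """Planar cell area in square degrees."""
        return self.cell_size_lon * self.cell_size_lat

    def lon_edges(self) -> np.ndarray:
        return self.origin_lon + self.cell_size_lon * np.arange(self.n_cols + 1)

    def lat_edges(self) -> np.ndarray:
        return self.origin_lat + self.cell_size_lat * np.arange(self.n_rows + 1)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + self.cell_size_lon * (np.arange(self.n_cols) + 0.5)

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat + self.cell_size_lat * (np.arange(self.n_rows) + 0.5)

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        """Shapely box for one cell footprint."""
        lon0 = self.origin_lon + col * self.cell_size_lon
        lat0 = self.origin_lat + row * self.cell_size_lat
        return box(lon0, lat0, lon0 + self.cell_size_lon, lat0 + self.cell_size_lat)

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the grid footprint."""
        return (
            self.origin_lon,
            self.origin_lat,
            self.origin_lon + self.n_cols * self.cell_size_lon,
            self.origin_lat + self.n_rows * self.cell_size_lat,
        )


@dataclass
class RasterField:
    """A per-cell value layer on a :class:`GridSpec`.

    ``values`` is float for continuous fields (missing cells are NaN and
    mirrored in ``missing``) or any dtype for categorical fields, in which
    case ``categories`` enumerates the legal classes and ``missing`` is the
    only missingness marker.
    """

    grid: GridSpec
    values: np.ndarray
    missing: np.ndarray | None = None
    units: str = ""
    categories: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.missing is None:
            if np.issubdtype(self.values.dtype, np.floating):
                self.missing = np.isnan(self.values)
            else:
                self.missing = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.grid.shape:
                raise ValueError("missing mask shape does not match grid")
        if self.categories is not None:
            present = set(np.unique(self.values[~self.missing]).tolist())
            illegal = present - set(self.categories)
            if illegal:
                raise ValueError(f"values outside declared categories: {sorted(illegal)}")

    @property
    def is_categorical(self) -> bool:
        return self.categories is not None

    def with_values(self, values: np.ndarray, **kw) -> "RasterField":
        out = RasterField(self.grid, values, units=kw.pop("units", self.units),
                          categories=kw.pop("categories", self.categories), **kw)
        return out


@dataclass
class RegionMap:
    """Named sub-region polygons plus the per-cell assignment on one grid."""

    grid: GridSpec
    polygons: dict[str, BaseGeometry]
    cell_assignment: np.ndarray  # dtype object/str; UNASSIGNED for no overlap

    def __post_init__(self) -> None:
        if self.cell_assignment.shape != self.grid.shape:
            raise ValueError("cell_assignment shape does not match grid")
        names = list(self.polygons)
        if len(names) != len(set(names)):
            raise ValueError("sub-region names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.polygons)

    def cells_of(self, name: str) -> np.ndarray:
        """Boolean mask of cells assigned to ``name``."""
        return self.cell_assignment == name

    def assigned_mask(self) -> np.ndarray:
        return self.cell_assignment != UNASSIGNED


def _validate_polygons(polygons: Mapping[str, BaseGeometry]) -> None:
    if not polygons:
        raise ValueError("polygon set is empty")
    for name, geom in polygons.items():
        if geom.is_empty or geom.area == 0:
            raise ValueError(f"degenerate (zero-area) polygon: {name!r}")
        if not geom.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon: {name!r}")


def assign_cells(grid: GridSpec, polygons: Mapping[str, BaseGeometry]) -> RegionMap:
    """Assign every grid cell to the sub-region with the greatest overlap area.

    Cells whose footprint does not overlap any polygon stay unassigned.  Ties
    are broken by polygon order (first named wins), which only matters for
    exact 50/50 straddles.
    """
    _validate_polygons(polygons)
    names = list(polygons)
    lon_e = grid.lon_edges()
    lat_e = grid.lat_edges()
    # all cell boxes, row-major
    jj, ii = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    boxes = shapely.box(
        lon_e[ii.ravel()], lat_e[jj.ravel()],
        lon_e[ii.ravel() + 1], lat_e[jj.ravel() + 1],
    )
    best_area = np.zeros(grid.n_cells)
    best_idx = np.full(grid.n_cells, -1)
    for k, name in enumerate(names):
        areas = shapely.area(shapely.intersection(boxes, polygons[name]))
        better = areas > best_area + 0.0  # strict: ties keep the earlier polygon
        best_area = np.where(better, areas, best_area)
        best_idx = np.where(better, k, best_idx)
    assignment = np.array(
        [names[k] if k >= 0 else UNASSIGNED for k in best_idx], dtype=object
    ).reshape(grid.shape)
    return RegionMap(grid=grid, polygons=dict(polygons), cell_assignment=assignment)


def _interval_overlap(edges_a: np.ndarray, edges_b: np.ndarray) -> np.ndarray:
    """Pairwise overlap length between intervals of two edge vectors.

    Returns matrix O[i, j] = |[a_i, a_{i+1}) ∩ [b_j, b_{j+1})|.
    """
    lo = np.maximum(edges_a[:-1, None], edges_b[None, :-1])
    hi = np.minimum(edges_a[1:, None], edges_b[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid(field: RasterField, target: GridSpec, method: str = "nearest") -> RasterField:
    """Resample a raster field onto another grid.

    Methods: ``area_weighted_mean`` (intensive), ``sum_conserving``
    (extensive, conserves the total over the shared domain), ``majority``
    (categorical only) and ``nearest`` (value of the source cell containing
    the target cell centre).
    """
    src = field.grid
    sb, tb = src.bounds(), target.bounds()
    if sb[2] <= tb[0] or tb[2] <= sb[0] or sb[3] <= tb[1] or tb[3] <= sb[1]:
        raise ValueError("source and target grids are disjoint")
    if method == "majority" and not field.is_categorical:
        raise ValueError("majority regridding requires a categorical field")
    if method in ("area_weighted_mean", "sum_conserving") and field.is_categorical:
        raise ValueError(f"{method} regridding requires a continuous field")

    if method == "nearest":
        lon_c, lat_c = target.lon_centers(), target.lat_centers()
        ci = np.floor((lon_c - src.origin_lon) / src.cell_size_lon).astype(int)
        rj = np.floor((lat_c - src.origin_lat) / src.cell_size_lat).astype(int)
        in_lon = (ci >= 0) & (ci < src.n_cols)
        in_lat = (rj >= 0) & (rj < src.n_rows)
        ci_c, rj_c = np.clip(ci, 0, src.n_cols - 1), np.clip(rj, 0, src.n_rows - 1)
        vals = field.values[np.ix_(rj_c, ci_c)]
        miss = field.missing[np.ix_(rj_c, ci_c)] | ~(in_lat[:, None] & in_lon[None, :])
        if np.issubdtype(np.asarray(vals).dtype, np.floating):
            vals = np.where(miss, np.nan, vals)
        return RasterField(target, vals, missing=miss, units=field.units,
                           categories=field.categories)

    # overlap factorises along axes for rectilinear grids
    o_lat = _interval_overlap(target.lat_edges(), src.lat_edges())  # (tr, sr)
    o_lon = _interval_overlap(target.lon_edges(), src.lon_edges())  # (tc, sc)

    if method == "majority":
        vals = np.empty(target.shape, dtype=field.values.dtype)
        miss = np.ones(target.shape, dtype=bool)
        cats = list(field.categories)
        src_ok = ~field.missing
        for tr in range(target.n_rows):
            wr = o_lat[tr]
            if not wr.any():
                continue
            for tc in range(target.n_cols):
                wc = o_lon[tc]
                w = np.outer(wr, wc) * src_ok
                total = w.sum()
                if total <= 0:
                    continue
                best_cat, best_a = None, 0.0
                for cat in cats:
                    a = w[field.values == cat].sum()
                    if a > best_a:
                        best_cat, best_a = cat, a
                vals[tr, tc] = best_cat
                miss[tr, tc] = False
        return RasterField(target, vals, missing=miss, units=field.units,
                           categories=field.categories)

    v = np.where(field.missing, 0.0, field.values.astype(float))
    ok = (~field.missing).astype(float)
    if method == "area_weighted_mean":
        wsum = o_lat @ ok @ o_lon.T
        vsum = o_lat @ (v * ok) @ o_lon.T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wsum > 0, vsum / wsum, np.nan)
        return RasterField(target, out, units=field.units)
    if method == "sum_conserving":
        # spread each source cell's quantity by the fraction of its area in
        # each target cell; missing source cells contribute nothing
        frac_lat = o_lat / src.cell_size_lat
        frac_lon = o_lon / src.cell_size_lon
        out = frac_lat @ (v * ok) @ frac_lon.T
        wsum = o_lat @ ok @ o_lon.T
        out = np.where(wsum > 0, out, np.nan)
        return RasterField(target, out, units=field.units)
    raise ValueError(f"unknown regrid method: {method!r}")


_STATS = {
    "mean": np.mean,
    "sum": np.sum,
    "min": np.min,
    "max": np.max,
}


def zonal_stat(
    field: RasterField,
    regions: RegionMap,
    stat: str = "mean",
    mask: RasterField | None = None,
) -> pd.DataFrame:
    """Per-region statistic over non-missing, mask-passing cells.

    ``mask`` (boolean/values>0 raster on the same grid) restricts the cells
    that contribute.  A region with no contributing cell gets a NaN value and
    ``n_cells`` 0 — missing, never silently zero.
    """
    if field.grid != regions.grid:
        raise ValueError("field and regions are on different grids")
    if mask is not None and mask.grid != field.grid:
        raise ValueError("mask is on a different grid")
    if stat not in _STATS:
        raise ValueError(f"unknown stat {stat!r}")
    fn = _STATS[stat]
    keep = ~field.missing
    if mask is not None:
        keep &= ~mask.missing & (mask.values.astype(bool) if mask.values.dtype != bool
                                 else mask.values)
    rows = []
    for name in regions.names:
        sel = regions.cells_of(name) & keep
        n = int(sel.sum())
        val = float(fn(field.values[sel].astype(float))) if n else float("nan")
        rows.append({"region": name, "stat": stat, "value": val, "n_cells": n})
    return pd.DataFrame(rows)
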