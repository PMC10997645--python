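"""Exposed-stock preparation: production rasters, survey conversion, seasonal split.

The production input is an annual tonnes-per-cell raster for a base year
(emulating the SPAM-style allocation product).  Two adjustments align it
with the study year and the growing calendar:

* **conversion factors** — multiplicative, per parent region, derived from
  how regional production changed between two national agricultural surveys,
  interpolated linearly in time to the study year;
* **seasonal split** — per sub-region shares dividing annual production into
  the two harvests (default 60:40 nationally), with unimodal sub-regions
  routing all production to their single season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, RasterField, RegionMap, UNASSIGNED

__all__ = [
    "ProductionRaster",
    "ConversionFactorTable",
    "SeasonalSplitTable",
    "apply_conversion",
    "derive_conversion_factors",
    "split_seasons",
    "DEFAULT_SEASON_SHARES",
]

#: national default harvest shares (season1, season2)
DEFAULT_SEASON_SHARES = (0.6, 0.4)

_SEASON_LABELS = ("annual", "season1", "season2", "unimodal")


@dataclass
class ProductionRaster(RasterField):
    """Tonnes of crop production per cell, annual or per season."""

    year: int | None = None
    season: str = "annual"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.season not in _SEASON_LABELS:
            raise ValueError(f"season must be one of {_SEASON_LABELS}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("production must be non-negative")
        if not self.units:
            self.units = "t"


@dataclass
class ConversionFactorTable:
    """Region name -> multiplicative factor mapping base-year to target-year."""

    factors: dict[str, float]
    base_year: int | None = None
    target_year: int | None = None
    method: str = "given"

    def __post_init__(self) -> None:
        for region, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"conversion factor for {region!r} must be positive")

    def __getitem__(self, region: str) -> float:
        return self.factors[region]


@dataclass
class SeasonalSplitTable:
    """Sub-region -> (share_season1, share_season2); unimodal = (1, 0) flagged."""

    shares: dict[str, tuple[float, float]]
    unimodal: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.unimodal = frozenset(self.unimodal)
        for name, (s1, s2) in self.shares.items():
            if s1 < 0 or s2 < 0 or abs(s1 + s2 - 1.0) > 1e-9:
                raise ValueError(
                    f"season shares for {name!r} must be non-negative and sum to 1 "
                    f"(got {s1}, {s2})"
                )
        for name in self.unimodal:
            if name in self.shares and self.shares[name] != (1.0, 0.0):
                raise ValueError(f"unimodal sub-region {name!r} must carry shares (1, 0)")

    def share(self, sub_region: str) -> tuple[float, float]:
        if sub_region in self.unimodal:
            return (1.0, 0.0)
        return self.shares[sub_region]

    @classmethod
    def with_defaults(
        cls,
        sub_regions: list[str],
        overrides: dict[str, tuple[float, float]] | None = None,
        unimodal: set[str] | frozenset[str] = frozenset(),
    ) -> "SeasonalSplitTable":
        shares = {}
        for name in sub_regions:
            if name in unimodal:
                shares[name] = (1.0, 0.0)
            elif overrides and name in overrides:
                shares[name] = tuple(overrides[name])
            else:
                shares[name] = DEFAULT_SEASON_SHARES
        return cls(shares=shares, unimodal=frozenset(unimodal))


def apply_conversion(
    raster: ProductionRaster,
    factors: ConversionFactorTable,
    regions: RegionMap,
    region_lookup: dict[str, str],
) -> ProductionRaster:
    """Scale each cell by its parent region's conversion factor.

    ``region_lookup`` maps sub-region names to parent-region names (the level
    at which survey totals, hence factors, exist).  Unassigned cells are left
    unchanged.
    """
    if raster.grid != regions.grid:
        raise ValueError("raster and regions are on different grids")
    needed = {
        region_lookup[sr]
        for sr in np.unique(regions.cell_assignment)
        if sr != UNASSIGNED
    }
    missing = sorted(needed - set(factors.factors))
    if missing:
        raise KeyError(f"no conversion factor for region(s): {missing}")
    out = raster.values.astype(float).copy()
    for sub_region in np.unique(regions.cell_assignment):
        if sub_region == UNASSIGNED:
            continue
        f = factors[region_lookup[sub_region]]
        sel = regions.cell_assignment == sub_region
        out[sel] = out[sel] * f
    return ProductionRaster(
        grid=raster.grid, values=out, missing=raster.missing.copy(),
        units=raster.units, year=factors.target_year, season=raster.season,
    )


def derive_conversion_factors(
    survey_early: dict[str, float],
    survey_late: dict[str, float],
    target_year: int,
    early_year: int,
    late_year: int,
    base_year: int | None = None,
) -> ConversionFactorTable:
    """Conversion factors from two survey snapshots, linear in time.

    Per region the survey totals are interpolated linearly between the two
    survey years; the factor maps the base-dataset year (default: the late
    survey year) to the target year:
    ``factor = interp(target_year) / interp(base_year)``.  A region whose
    production did not change between surveys gets factor 1 regardless of
    years.
    """
    if set(survey_early) != set(survey_late):
        raise ValueError("survey snapshots cover different region sets")
    if not (early_year < target_year < late_year):
        raise ValueError("require early_year < target_year < late_year")
    if base_year is None:
        base_year = late_year
    factors = {}
    for region in survey_early:
        p0, p1 = float(survey_early[region]), float(survey_late[region])
        if p0 <= 0:
            raise ValueError(f"non-positive early-survey production for {region!r}")
        if p1 < 0:
            raise ValueError(f"negative late-survey production for {region!r}")

        def interp(year: float) -> float:
            return p0 + (p1 - p0) * (year - early_year) / (late_year - early_year)

        denom = interp(base_year)
        if denom <= 0:
            raise ValueError(f"interpolated base-year production non-positive for {region!r}")
        factors[region] = interp(target_year) / denom
    return ConversionFactorTable(
        factors=factors, base_year=base_year, target_year=target_year,
        method=f"linear-interpolation-{early_year}-{late_year}",
    )


def split_seasons(
    raster: ProductionRaster,
    splits: SeasonalSplitTable,
    regions: RegionMap,
) -> tuple[ProductionRaster, ProductionRaster]:
    """Divide an annual raster into per-season rasters, conserving tonnes.

    Cellwise ``season_k = annual * share_k`` using the cell's sub-region
    shares; unimodal sub-regions route everything to their single window
    (returned in the season-1 slot and assessed with their own window
    downstream).  Splitting an already-split raster is refused.
    """
    if raster.season != "annual":
        raise ValueError("can only split an annual raster (already split?)")
    if raster.grid != regions.grid:
        raise ValueError("raster and regions are on different grids")
    assigned = [s for s in np.unique(regions.cell_assignment) if s != UNASSIGNED]
    missing = [s for s in assigned if s not in splits.shares and s not in splits.unimodal]
    if missing:
        raise KeyError(f"no season split for sub-region(s): {missing}")
    s1 = np.zeros(raster.grid.shape)
    s2 = np.zeros(raster.grid.shape)
    vals = raster.values.astype(float)
    for sub_region in assigned:
        sel = regions.cell_assignment == sub_region
        share1, share2 = splits.share(sub_region)
        s1[sel] = vals[sel] * share1
        s2[sel] = vals[sel] * share2
    unassigned = regions.cell_assignment == UNASSIGNED
    s1[unassigned] = vals[unassigned] * DEFAULT_SEASON_SHARES[0]
    s2[unassigned] = vals[unassigned] * DEFAULT_SEASON_SHARES[1]
    mk = lambda v, season: ProductionRaster(
        grid=raster.grid, values=v, missing=raster.missing.copy(),
        units=raster.units, year=raster.year, season=season,
    )
    return mk(s1, "season1"), mk(s2, "season2")
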