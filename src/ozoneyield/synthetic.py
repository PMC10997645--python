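"""Synthetic study inputs with controllable ground truth.

Generates every input the assessment pipeline consumes — a daily ozone-dose
cube on a coarse grid, a patchy production raster on a fine grid, a
rectangular partition of the domain into named sub-regions grouped into
parent regions, survey tables, and the six stress layers — so the whole
pipeline runs and is testable offline.

The default scenario mirrors the scales of the study system: a coarse
~0.3 deg exposure grid over a ~4.8 x 4.2 deg equatorial domain, a fine
0.0833 deg production grid, 14 sub-regions in 4 parent regions with one
unimodal sub-region.  What the generator emulates is the *statistical
structure* of the real inputs (a smooth north-west-high dose field with a
seasonal cycle, log-normal patchy production, ordinal/continuous stress
surfaces with spatial gradients) — not the geography of any real country.

All randomness flows from one seed through named substreams, so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import FluxCube
from .grid import GridSpec, RasterField, RegionMap, assign_cells
from .production import ProductionRaster
from .stress import SOIL_CLASSES, StressLayer, flood_layer_from_districts

from shapely.geometry import box

__all__ = [
    "SyntheticScenario",
    "gen_flux_cube",
    "gen_production",
    "gen_regions",
    "gen_stress_layers",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stream name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, *stream.encode()]))


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int = 0
    year: int = 2015
    # grids: coarse exposure, fine production
    coarse_grid: GridSpec = field(
        default_factory=lambda: GridSpec(29.7, -1.5, 0.3, 0.3, 16, 14)
    )
    fine_grid: GridSpec = field(
        default_factory=lambda: GridSpec(29.7, -1.5, 0.0833, 0.0833, 57, 50)
    )
    # region partition: sub-regions per horizontal band, south to north
    layout: tuple[int, ...] = (4, 4, 3, 3)
    n_parent_regions: int = 4
    unimodal_index: int | None = 13  # last sub-region plays the unimodal role
    # dose model, mmol m-2 d-1
    pod_baseline: float = 0.10
    pod_gradient: float = 0.12  # added at the NW corner, fading to 0 at SE
    pod_seasonal_amplitude: float = 0.05
    pod_noise_sd: float = 0.02
    # production model
    occupancy: float = 0.6
    mean_tonnes: float = 40.0
    dispersion: float = 0.8  # sigma of the log-normal
    # survey factors applied to the generated base-year regional sums
    survey_early_factor: float = 0.8
    survey_late_factor: float = 1.1
    # stress layer controls; "benign" pins every layer at its lowest-risk value
    stress_benign: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be within [0, 1]")
        if self.pod_baseline < 0:
            raise ValueError("pod_baseline must be non-negative")
        if sum(self.layout) < 1:
            raise ValueError("layout must define at least one sub-region")

    @property
    def n_sub_regions(self) -> int:
        return sum(self.layout)


def _nw_distance(grid: GridSpec) -> np.ndarray:
    """1 at the north-west corner fading linearly to 0 at the south-east."""
    x = (np.arange(grid.n_cols) + 0.5) / grid.n_cols  # 0 west -> 1 east
    y = (np.arange(grid.n_rows) + 0.5) / grid.n_rows  # 0 south -> 1 north
    return ((1.0 - x)[None, :] + y[:, None]) / 2.0


def gen_flux_cube(scenario: SyntheticScenario) -> FluxCube:
    """Daily POD-increment cube for the scenario year.

    Per cell and day: ``max(0, baseline + gradient*nw + seasonal + noise)``
    where the seasonal term is a sinusoid over the calendar year and ``nw``
    is the normalised distance-from-south-east surface (dose is highest in
    the north-west, as in the emulated exposure fields).
    """
    grid = scenario.coarse_grid
    time = pd.date_range(f"{scenario.year}-01-01", f"{scenario.year}-12-31", freq="D")
    doy = time.dayofyear.to_numpy()
    seasonal = scenario.pod_seasonal_amplitude * np.sin(2 * np.pi * (doy - 30) / 365.25)
    base = scenario.pod_baseline + scenario.pod_gradient * _nw_distance(grid)
    rng = _rng(scenario.seed, "flux")
    noise = (
        rng.normal(0.0, scenario.pod_noise_sd, size=(len(time),) + grid.shape)
        if scenario.pod_noise_sd > 0 else 0.0
    )
    values = np.clip(base[None, :, :] + seasonal[:, None, None] + noise, 0.0, None)
    return FluxCube(grid=grid, time=time, values=values, mode="daily")


def gen_regions(scenario: SyntheticScenario) -> tuple[dict, dict[str, str], RegionMap]:
    """Rectangular sub-region partition of the fine-grid domain.

    Returns (polygons, sub-region -> parent-region lookup, RegionMap on the
    fine grid).  The domain is cut into horizontal bands (one per entry of
    ``layout``), each band into equal-width rectangles west to east.
    Parent regions are assigned band-wise, round-robin over
    ``n_parent_regions``.
    """
    grid = scenario.fine_grid
    min_lon, min_lat, max_lon, max_lat = grid.bounds()
    n_bands = len(scenario.layout)
    band_edges = np.linspace(min_lat, max_lat, n_bands + 1)
    polygons: dict = {}
    lookup: dict[str, str] = {}
    k = 0
    for b, n_in_band in enumerate(scenario.layout):
        lon_edges = np.linspace(min_lon, max_lon, n_in_band + 1)
        for i in range(n_in_band):
            name = f"SR{k + 1:02d}"
            polygons[name] = box(lon_edges[i], band_edges[b], lon_edges[i + 1], band_edges[b + 1])
            lookup[name] = f"R{(b % scenario.n_parent_regions) + 1}"
            k += 1
    rmap = assign_cells(grid, polygons)
    if not rmap.assigned_mask().all():
        raise ValueError("region partition does not cover the grid")
    return polygons, lookup, rmap


def unimodal_name(scenario: SyntheticScenario) -> str | None:
    if scenario.unimodal_index is None:
        return None
    return f"SR{scenario.unimodal_index + 1:02d}"


def gen_production(
    scenario: SyntheticScenario, regions: RegionMap, lookup: dict[str, str]
) -> tuple[ProductionRaster, pd.DataFrame]:
    """Patchy base-year production raster plus consistent survey tables.

    Cells are occupied with probability ``occupancy``; occupied cells draw
    log-normal tonnage with the configured mean.  The survey table holds,
    per parent region, the raster's exact regional sum ("base") and the two
    survey snapshots obtained by scaling it with the stated early/late
    factors — so factor derivation has a known truth.
    """
    grid = scenario.fine_grid
    rng = _rng(scenario.seed, "production")
    occupied = rng.random(grid.shape) < scenario.occupancy
    if scenario.dispersion > 0:
        sigma = scenario.dispersion
        mu = np.log(scenario.mean_tonnes) - sigma**2 / 2.0
        tonnes = rng.lognormal(mu, sigma, size=grid.shape)
    else:
        tonnes = np.full(grid.shape, float(scenario.mean_tonnes))
    values = np.where(occupied, tonnes, 0.0)
    raster = ProductionRaster(grid=grid, values=values, units="t", year=None,
                              season="annual")
    parent_regions = sorted(set(lookup.values()))
    rows = []
    for pr in parent_regions:
        sel = np.isin(regions.cell_assignment, [s for s, p in lookup.items() if p == pr])
        base = float(values[sel].sum())
        rows.append({
            "region": pr,
            "base": base,
            "survey_early": base * scenario.survey_early_factor,
            "survey_late": base * scenario.survey_late_factor,
        })
    return raster, pd.DataFrame(rows)


def gen_stress_layers(
    scenario: SyntheticScenario, regions: RegionMap
) -> list[StressLayer]:
    """The six stress layers on the fine grid, with seeded spatial structure.

    Value ranges match the emulated products: SPEI within [-2.5, 2.5],
    deprivation within [0, 100], temperature roughly 20-38 deg C, flood
    counts small non-negative integers per district, five ordered soil
    classes, and an ozone yield-loss surface in percent.  With
    ``stress_benign`` every layer sits at its lowest-risk value, so the
    composite score is exactly 6 everywhere.
    """
    grid = scenario.fine_grid
    nw = _nw_distance(grid)
    layers: list[StressLayer] = []

    if scenario.stress_benign:
        soil_vals = np.full(grid.shape, SOIL_CLASSES[0], dtype=object)
        spei = np.full(grid.shape, 1.0)
        temp = np.full(grid.shape, 24.0)
        depr = np.full(grid.shape, 5.0)
        ozone = np.full(grid.shape, 1.0)
        counts = {name: 0.0 for name in regions.polygons}
    else:
        rng = _rng(scenario.seed, "stress")
        soil_idx = np.clip(
            np.floor((1 - nw) * 5 + rng.normal(0, 0.7, grid.shape)), 0, 4
        ).astype(int)
        soil_vals = np.array(SOIL_CLASSES, dtype=object)[soil_idx]
        spei = np.clip(1.5 - 3.0 * (1 - nw) + rng.normal(0, 0.3, grid.shape), -2.5, 2.5)
        temp = 21.0 + 15.0 * nw + rng.normal(0, 1.0, grid.shape)
        depr = np.clip(30.0 + 55.0 * nw + rng.normal(0, 8.0, grid.shape), 0.0, 100.0)
        ozone = np.clip(3.0 + 22.0 * nw + rng.normal(0, 1.5, grid.shape), 0.0, 99.9)
        flood_rng = _rng(scenario.seed, "flood")
        counts = {name: float(flood_rng.poisson(2.0)) for name in regions.polygons}

    layers.append(StressLayer(
        "soil_nutrient",
        RasterField(grid, soil_vals, categories=SOIL_CLASSES),
        source="synthetic",
    ))
    layers.append(StressLayer("spei", RasterField(grid, spei, units="SPEI"),
                              period="6-month", source="synthetic"))
    layers.append(flood_layer_from_districts(regions.polygons, counts, grid))
    layers.append(StressLayer("temperature", RasterField(grid, temp, units="degC"),
                              source="synthetic"))
    layers.append(StressLayer("deprivation", RasterField(grid, depr, units="index"),
                              source="synthetic"))
    layers.append(StressLayer("ozone_yl", RasterField(grid, ozone, units="%"),
                              source="synthetic"))
    return layers
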