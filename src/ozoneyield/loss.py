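"""Production-loss accounting and sub-region / national reporting.

Yield loss removes a fraction of what would have been harvested, so the
observed tonnage ``P`` under a percentage loss ``yl`` relates to the
pre-loss potential by ``potential = P / (1 - yl/100)`` and the foregone
tonnage is

    loss = P / (1 - yl/100) - P = P * yl / (100 - yl).

The assessment applies the flux-effect relationship per cell and season,
converts to tonnes with the seasonal production raster, and reports:

* sub-region mean percentage yield loss over cells *with production data*
  (zero-production cells included — they mark land that could grow the crop);
* sub-region production losses summed over cells with production > 0;
* national rows aggregated at cell level (mean over all contributing cells,
  sum of all losses) — deliberately not a mean of sub-region means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import FluxEffectModel, yield_loss, YIELD_LOSS_CAP
from .exposure import PODField
from .grid import RasterField, RegionMap
from .production import ProductionRaster

__all__ = [
    "relative_yield",
    "production_loss",
    "run_assessment",
    "aggregate_loss_table",
    "AssessmentResult",
    "NATIONAL_LABEL",
]

NATIONAL_LABEL = "Total"


def relative_yield(yield_loss_pct, literal_eq2: bool = False):
    """Fractional yield retained under a percentage loss.

    The standard reading is ``RY = 1 - %YL/100``.  ``literal_eq2`` switches
    to the alternative printed form ``RY = 1/(%YL/100)`` for auditability;
    it is not meaningful at 0% loss and produces non-physical losses, and
    exists only so the two readings can be compared explicitly.
    """
    arr = np.asarray(yield_loss_pct, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > YIELD_LOSS_CAP)
        if bool(np.any(bad & ~np.isnan(arr))):
            raise ValueError(f"yield loss must be within [0, {YIELD_LOSS_CAP}] %")
    if literal_eq2:
        with np.errstate(divide="ignore"):
            ry = np.where(arr > 0, 100.0 / arr, np.inf)
    else:
        ry = 1.0 - arr / 100.0
    if np.ndim(yield_loss_pct) == 0:
        return float(ry)
    return ry


def production_loss(production_t, yield_loss_pct, literal_eq2: bool = False):
    """Tonnes foregone: ``P / RY - P`` = ``P * yl / (100 - yl)``."""
    p = np.asarray(production_t, dtype=float)
    with np.errstate(invalid="ignore"):
        if bool(np.any((p < 0) & ~np.isnan(p))):
            raise ValueError("production must be non-negative")
    ry = relative_yield(yield_loss_pct, literal_eq2=literal_eq2)
    with np.errstate(invalid="ignore", divide="ignore"):
        loss = p / ry - p
    loss = np.where(p == 0, 0.0, loss)
    if np.ndim(production_t) == 0 and np.ndim(yield_loss_pct) == 0:
        return float(loss)
    return loss


@dataclass
class AssessmentResult:
    """Loss table plus the per-cell rasters behind it."""

    table: pd.DataFrame
    yield_loss_rasters: dict[str, RasterField]
    production_loss_rasters: dict[str, RasterField]
    n_pod_missing: dict[str, int]


def _season_cells(
    pod: PODField,
    model: FluxEffectModel,
    production: ProductionRaster,
    literal_eq2: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell %YL and loss (t) for one season; NaN where not computable."""
    yl = yield_loss(pod, model)
    prod = np.where(production.missing, np.nan, production.values.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        ry = np.where(np.isnan(yl), np.nan, 1.0 - yl / 100.0)
        if literal_eq2:
            ry = np.where(yl > 0, 100.0 / yl, np.inf)
        loss = prod / ry - prod
    loss = np.where(prod == 0, 0.0, loss)
    loss = np.where(np.isnan(yl) | np.isnan(prod), np.nan, loss)
    return yl, loss


def run_assessment(
    pod_fields: dict[str, PODField],
    model: FluxEffectModel,
    production: dict[str, ProductionRaster],
    regions: RegionMap,
    region_lookup: dict[str, str] | None = None,
    unimodal: dict[str, str] | None = None,
    yl_mean_weighting: str = "none",
    literal_eq2: bool = False,
) -> AssessmentResult:
    """Full dose -> yield-loss -> production-loss assessment.

    ``pod_fields`` and ``production`` are keyed by season label ("season1",
    "season2", and optionally a unimodal window name).  ``unimodal`` maps
    each unimodal sub-region to the season key that assesses it; those
    sub-regions are excluded from the bimodal passes and their single-season
    loss is reported in the season-1 column of annual totals.
    ``yl_mean_weighting``: "none" (unweighted cell mean, default) or
    "production" (production-weighted).
    """
    if yl_mean_weighting not in ("none", "production"):
        raise ValueError("yl_mean_weighting must be 'none' or 'production'")
    unimodal = dict(unimodal or {})
    region_lookup = dict(region_lookup or {})
    for season, prod in production.items():
        expected = "unimodal" if season in unimodal.values() else season
        if prod.season not in (expected, season):
            raise ValueError(
                f"production raster labelled {prod.season!r} supplied for "
                f"season {season!r}"
            )
        if season not in pod_fields:
            raise ValueError(f"no POD field for season {season!r}")
        if prod.grid != regions.grid or pod_fields[season].grid != regions.grid:
            raise ValueError("all rasters must be on the regions grid (regrid first)")

    unimodal_seasons = set(unimodal.values())
    rows = []
    yl_rasters: dict[str, RasterField] = {}
    loss_rasters: dict[str, RasterField] = {}
    n_missing: dict[str, int] = {}
    # national accumulators at cell level
    nat_yl: dict[str, list[np.ndarray]] = {}
    nat_w: dict[str, list[np.ndarray]] = {}
    nat_loss: dict[str, float] = {}

    for season, prod in production.items():
        pod = pod_fields[season]
        yl, loss = _season_cells(pod, model, prod, literal_eq2)
        yl_rasters[season] = RasterField(regions.grid, yl, units="%")
        loss_rasters[season] = RasterField(regions.grid, loss, units="t")
        n_missing[season] = int(
            (np.isnan(pod.values) & ~prod.missing & regions.assigned_mask()).sum()
        )
        if season in unimodal_seasons:
            season_subs = [s for s, w in unimodal.items() if w == season]
        else:
            season_subs = [s for s in regions.names if s not in unimodal]
        for sub_region in season_subs:
            sel = regions.cells_of(sub_region)
            has_prod = sel & ~prod.missing  # cells with production data, incl. zero
            contributing = has_prod & ~np.isnan(yl)
            if yl_mean_weighting == "production":
                w = prod.values[contributing]
                mean_yl = (
                    float(np.average(yl[contributing], weights=w))
                    if contributing.any() and w.sum() > 0 else float("nan")
                )
            else:
                mean_yl = float(yl[contributing].mean()) if contributing.any() else float("nan")
            producing = contributing & (prod.values > 0)
            loss_t = float(np.nansum(loss[producing])) if producing.any() else 0.0
            prod_t = float(prod.values[contributing].sum()) if contributing.any() else 0.0
            rows.append({
                "sub_region": sub_region,
                "region": region_lookup.get(sub_region, ""),
                "season": season,
                "mean_yield_loss_pct": mean_yl,
                "production_t": prod_t,
                "production_loss_t": loss_t,
            })
            nat_yl.setdefault(season, []).append(yl[contributing])
            if yl_mean_weighting == "production":
                nat_w.setdefault(season, []).append(prod.values[contributing])
            nat_loss[season] = nat_loss.get(season, 0.0) + loss_t

    for season in production:
        cells = np.concatenate(nat_yl.get(season, [np.array([])]))
        if yl_mean_weighting == "production":
            w = np.concatenate(nat_w.get(season, [np.array([])]))
            mean_yl = float(np.average(cells, weights=w)) if cells.size and w.sum() > 0 else float("nan")
        else:
            mean_yl = float(cells.mean()) if cells.size else float("nan")
        rows.append({
            "sub_region": NATIONAL_LABEL,
            "region": "",
            "season": season,
            "mean_yield_loss_pct": mean_yl,
            "production_t": sum(
                r["production_t"] for r in rows
                if r["season"] == season and r["sub_region"] != NATIONAL_LABEL
            ),
            "production_loss_t": nat_loss.get(season, 0.0),
        })

    table = pd.DataFrame(rows)
    return AssessmentResult(
        table=table,
        yield_loss_rasters=yl_rasters,
        production_loss_rasters=loss_rasters,
        n_pod_missing=n_missing,
    )


def aggregate_loss_table(
    losses: pd.DataFrame,
    season1: str = "season1",
    season2: str = "season2",
) -> pd.DataFrame:
    """Annual and national totals from per-sub-region seasonal loss cells.

    Input: DataFrame with columns ``sub_region`` and one column per season
    holding production losses in tonnes (NaN where a sub-region is not
    assessed in that season, e.g. a unimodal sub-region's second season).
    Returns the table with a ``total`` column (rowwise sum over available
    seasons) and an appended national row summing every column.
    """
    for col in (season1, season2):
        if col not in losses.columns:
            raise KeyError(f"missing season column {col!r}")
    out = losses.copy()
    out["total"] = out[[season1, season2]].sum(axis=1, min_count=1)
    nat = {
        "sub_region": NATIONAL_LABEL,
        season1: out[season1].sum(min_count=1),
        season2: out[season2].sum(min_count=1),
        "total": out["total"].sum(min_count=1),
    }
    for col in out.columns:
        if col not in nat:
            nat[col] = ""
    return pd.concat([out, pd.DataFrame([nat])], ignore_index=True)
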