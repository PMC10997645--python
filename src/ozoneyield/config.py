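"""Run configuration and the end-to-end pipeline driver.

A run is described by a YAML config.  Two input modes exist: ``simulate``
(the synthetic generator provides every input, seeded) and explicit paths
(flux cube, annual production raster, region GeoJSON plus lookup/split
tables).  ``run_all`` executes accumulate -> yield loss -> production prep
-> assessment -> stress scoring, writes every artifact with a manifest of
checksums, and snapshots the fully resolved config next to the outputs so a
run is reproducible from the snapshot alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .dose_response import FluxEffectModel, default_model
from .exposure import PODField, SeasonWindow, accumulate_pod
from .grid import RasterField, assign_cells, regrid
from .loss import run_assessment
from .production import (
    ConversionFactorTable,
    ProductionRaster,
    SeasonalSplitTable,
    apply_conversion,
    derive_conversion_factors,
    split_seasons,
)
from .stress import ClassMap, composite_score
from .synthetic import (
    SyntheticScenario,
    gen_flux_cube,
    gen_production,
    gen_regions,
    gen_stress_layers,
    unimodal_name,
)

__all__ = ["RunConfig", "load_config", "run_all", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_KNOWN_KEYS = {
    "simulate", "seed", "year", "out_dir",
    "flux_cube", "production", "regions", "region_lookup",
    "model", "model_file",
    "seasons", "conversion_factors", "surveys",
    "season_splits", "unimodal_subregions",
    "regrid_method", "missing_policy", "yl_mean_weighting", "literal_eq2",
    "scoring_breakpoints", "run_stress",
}

_DEFAULTS = {
    "simulate": False,
    "seed": 0,
    "year": 2015,
    "out_dir": "results",
    "model": {"slope": 1.175, "intercept": 100.0, "reference_pod": 0.0},
    "seasons": {"season1": [91, 180], "season2": [257, 346], "karamoja": [182, 271]},
    "season_splits": {},
    "unimodal_subregions": [],
    "conversion_factors": None,
    "surveys": None,
    "regrid_method": "nearest",
    "missing_policy": "error",
    "yl_mean_weighting": "none",
    "literal_eq2": False,
    "scoring_breakpoints": {},
    "run_stress": True,
}


@dataclass
class RunConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])


def _validate(cfg: dict, source: str = "<config>") -> dict:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown config key(s): {sorted(unknown)}")
    merged = {**_DEFAULTS, **cfg}
    for name, days in merged["seasons"].items():
        if len(days) != 2 or not (1 <= days[0] <= days[1] <= 366):
            raise ConfigError(f"{source}: seasons.{name}: bad window {days}")
    for name, shares in merged["season_splits"].items():
        if len(shares) != 2 or abs(sum(shares) - 1.0) > 1e-9 or min(shares) < 0:
            raise ConfigError(
                f"{source}: season_splits.{name}: shares {shares} must be "
                "non-negative and sum to 1"
            )
    if merged["regrid_method"] not in ("nearest", "area_weighted_mean"):
        raise ConfigError(f"{source}: regrid_method must be nearest or area_weighted_mean")
    if merged["missing_policy"] not in ("error", "skip", "scale"):
        raise ConfigError(f"{source}: missing_policy must be error, skip or scale")
    if not merged["simulate"]:
        for key in ("flux_cube", "production", "regions"):
            if not merged.get(key):
                raise ConfigError(
                    f"{source}: {key} path is required unless simulate is true"
                )
    m = merged["model"]
    if "slope" in m and not np.isfinite(m["slope"]):
        raise ConfigError(f"{source}: model.slope must be finite")
    return merged


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and default-resolve a YAML run config."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        cfg = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"{p}: not parseable YAML: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError(f"{p}: config must be a mapping")
    return RunConfig(raw=_validate(cfg, source=str(p)))


def _model_from_config(cfg: RunConfig) -> FluxEffectModel:
    if cfg.get("model_file"):
        return oio.read_model(cfg["model_file"])
    m = cfg["model"]
    return FluxEffectModel(
        slope=float(m.get("slope", 1.175)),
        intercept=float(m.get("intercept", 100.0)),
        reference_pod=float(m.get("reference_pod", 0.0)),
        provenance="config",
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the artifact manifest.

    Steps, in order: obtain inputs (simulate or load), accumulate seasonal
    POD, sample POD onto the production grid, prepare seasonal production,
    run the loss assessment, score stresses, write everything with
    checksums.  Any step failure raises with the step name attached.
    """
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": [], "steps": []}

    def record(path: Path, step: str) -> None:
        manifest["artifacts"].append(
            {"file": str(path), "sha256": _sha256(path), "step": step}
        )

    def step(name: str):
        manifest["steps"].append(name)
        return name

    try:
        step("inputs")
        if config["simulate"]:
            scenario = SyntheticScenario(seed=config.seed, year=int(config["year"]))
            cube = gen_flux_cube(scenario)
            polygons, lookup, regions = gen_regions(scenario)
            production, surveys = gen_production(scenario, regions, lookup)
            uni = unimodal_name(scenario)
            unimodal_list = [uni] if uni else []
            factors = derive_conversion_factors(
                dict(zip(surveys["region"], surveys["survey_early"])),
                dict(zip(surveys["region"], surveys["survey_late"])),
                target_year=int(config["year"]), early_year=2009, late_year=2018,
            )
            stress_layers = gen_stress_layers(scenario, regions) if config["run_stress"] else None
        else:
            cube = oio.read_cube(config["flux_cube"])
            production = oio.read_production(config["production"])
            polygons, props = oio.read_regions(config["regions"])
            regions = assign_cells(production.grid, polygons)
            lookup = {
                name: p.get("region", name) for name, p in props.items()
            }
            if config.get("region_lookup"):
                lut = oio.read_table(config["region_lookup"])
                lookup = dict(zip(lut["sub_region"], lut["region"]))
            unimodal_list = list(config["unimodal_subregions"])
            if config["conversion_factors"]:
                factors = ConversionFactorTable(
                    {k: float(v) for k, v in config["conversion_factors"].items()}
                )
            elif config["surveys"]:
                sv = oio.read_table(config["surveys"])
                factors = derive_conversion_factors(
                    dict(zip(sv["region"], sv["survey_early"])),
                    dict(zip(sv["region"], sv["survey_late"])),
                    target_year=int(config["year"]),
                    early_year=int(sv["early_year"].iloc[0]),
                    late_year=int(sv["late_year"].iloc[0]),
                )
            else:
                factors = ConversionFactorTable({r: 1.0 for r in set(lookup.values())})
            stress_layers = None

        step("accumulate")
        windows = {
            name: SeasonWindow(name, int(d[0]), int(d[1]))
            for name, d in config["seasons"].items()
        }
        year = int(config["year"])
        pod_coarse = {
            name: accumulate_pod(cube, w, year, missing_policy=config["missing_policy"])
            for name, w in windows.items()
        }

        step("regrid")
        pod_fine: dict[str, PODField] = {}
        for name, podf in pod_coarse.items():
            fld = RasterField(podf.grid, podf.values, units="mmol m-2")
            re = regrid(fld, production.grid, method=config["regrid_method"])
            pod_fine[name] = PODField(production.grid, podf.window, re.values, year=year)
            p = out / f"pod_{name}.nc"
            oio.write_raster(
                RasterField(production.grid, pod_fine[name].values, units="mmol m-2"),
                p, name="pod",
            )
            record(p, "regrid")

        step("production")
        production_2015 = apply_conversion(production, factors, regions, lookup)
        splits = SeasonalSplitTable.with_defaults(
            regions.names,
            overrides={k: tuple(v) for k, v in config["season_splits"].items()},
            unimodal=set(unimodal_list),
        )
        prod_s1, prod_s2 = split_seasons(production_2015, splits, regions)
        season_prod = {"season1": prod_s1, "season2": prod_s2}
        unimodal_map: dict[str, str] = {}
        for uni in unimodal_list:
            win = "karamoja" if "karamoja" in windows else list(windows)[0]
            unimodal_map[uni] = win
            mask_vals = np.where(regions.cells_of(uni), prod_s1.values, 0.0)
            season_prod[win] = ProductionRaster(
                grid=prod_s1.grid, values=mask_vals, missing=prod_s1.missing.copy(),
                units=prod_s1.units, year=prod_s1.year, season="unimodal",
            )

        step("assess")
        model = _model_from_config(config)
        result = run_assessment(
            pod_fields=pod_fine, model=model, production=season_prod,
            regions=regions, region_lookup=lookup, unimodal=unimodal_map,
            yl_mean_weighting=config["yl_mean_weighting"],
            literal_eq2=bool(config["literal_eq2"]),
        )
        p = out / "loss_table.csv"
        oio.write_table(result.table, p,
                        comment="per sub-region and national ozone yield/production losses; tonnes")
        record(p, "assess")
        for season, fld in result.yield_loss_rasters.items():
            p = out / f"yield_loss_{season}.nc"
            oio.write_raster(fld, p, name="yield_loss_pct")
            record(p, "assess")
        for season, fld in result.production_loss_rasters.items():
            p = out / f"production_loss_{season}.nc"
            oio.write_raster(fld, p, name="production_loss_t")
            record(p, "assess")

        if config["run_stress"] and stress_layers is not None:
            step("stress")
            maps = {}
            for lname, spec_bp in config["scoring_breakpoints"].items():
                maps[lname] = ClassMap(breakpoints=tuple(spec_bp.get("breakpoints", ())),
                                       higher_is_worse=bool(spec_bp.get("higher_is_worse", True)))
            score = composite_score(stress_layers, class_maps=maps or None)
            p = out / "stress_composite.nc"
            oio.write_raster(RasterField(score.grid, score.composite, units="score"),
                             p, name="crop_stress_score")
            record(p, "stress")

        step("finalise")
        resolved = out / "resolved.yaml"
        resolved.write_text(yaml.safe_dump(config.raw, sort_keys=True))
        record(resolved, "finalise")
        manifest["status"] = 0
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as e:
        failed = manifest["steps"][-1] if manifest["steps"] else "init"
        raise RuntimeError(f"pipeline failed at step {failed!r}: {e}") from e
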