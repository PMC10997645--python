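"""Composite crop-stress scoring.

Each stress layer — soil-nutrient constraint class, drought (SPEI),
flood occurrence, growing-season maximum temperature, deprivation index and
ozone yield loss — is scored on an ordinal 1..5 scale (very low to very
high risk to crop yield) and the scores are summed into a per-cell
composite crop-stress score.  With six layers the composite ranges 6..30.
No interaction between stresses is modelled: the composite flags
co-location, nothing more.

Default breakpoints are artifact defaults, overrideable in config:

* soil: the five constraint classes map to 1..5 in ladder order;
* SPEI (6-month, lower is worse): >= 0 -> 1 down to < -1.5 -> 5, following
  the standard SPEI dryness categories;
* flood occurrence count: 0 -> 1, 1 -> 2, 2-3 -> 3, 4-5 -> 4, >= 6 -> 5;
* temperature (mean daily max, deg C): < 28 -> 1 up to >= 35 -> 5, anchored
  on bean physiology (optimal up to 28, tolerated to 29.5, blossom abortion
  near 35);
* deprivation (0-100): quintiles 1..5;
* ozone yield loss (%): 0-5 -> 1, 5-10 -> 2, 10-16 -> 3, 16-22 -> 4,
  > 22 -> 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec, RasterField, assign_cells, UNASSIGNED

__all__ = [
    "StressLayer",
    "ScoreMap",
    "ClassMap",
    "score_layer",
    "flood_layer_from_districts",
    "composite_score",
    "default_class_maps",
    "SOIL_CLASSES",
]

LAYER_NAMES = ("soil_nutrient", "spei", "flood", "temperature", "deprivation", "ozone_yl")

SOIL_CLASSES = (
    "No constraints",
    "Slight constraints",
    "Moderate constraints",
    "Severe constraints",
    "Very severe constraints",
)


@dataclass
class StressLayer:
    name: str
    field: RasterField
    period: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown stress layer {self.name!r}; expected one of {LAYER_NAMES}")


@dataclass
class ClassMap:
    """How a layer's values map onto 1..5 scores.

    Continuous layers use ordered ``breakpoints`` (length 4) that cut the
    real line into 5 half-open bins: with ``higher_is_worse`` the bins are
    ``(-inf, b0) [b0, b1) ... [b3, inf)`` scored 1..5; with the orientation
    flipped the same bins score 5..1.  Categorical layers use an explicit
    ``category_scores`` table.
    """

    breakpoints: tuple[float, ...] | None = None
    higher_is_worse: bool = True
    category_scores: dict | None = None

    def __post_init__(self) -> None:
        if (self.breakpoints is None) == (self.category_scores is None):
            raise ValueError("provide exactly one of breakpoints or category_scores")
        if self.breakpoints is not None:
            bp = tuple(float(b) for b in self.breakpoints)
            if list(bp) != sorted(bp):
                raise ValueError("breakpoints must be increasing")
            if len(bp) != 4:
                raise ValueError("need exactly 4 breakpoints for 5 classes")
            self.breakpoints = bp
        if self.category_scores is not None:
            for cat, s in self.category_scores.items():
                if not (1 <= int(s) <= 5):
                    raise ValueError(f"score for {cat!r} outside 1..5")


def default_class_maps() -> dict[str, ClassMap]:
    return {
        "soil_nutrient": ClassMap(
            category_scores={c: i + 1 for i, c in enumerate(SOIL_CLASSES)}
        ),
        "spei": ClassMap(breakpoints=(-1.5, -1.0, -0.5, 0.0), higher_is_worse=False),
        "flood": ClassMap(breakpoints=(1.0, 2.0, 4.0, 6.0), higher_is_worse=True),
        "temperature": ClassMap(breakpoints=(28.0, 29.5, 32.0, 35.0), higher_is_worse=True),
        "deprivation": ClassMap(breakpoints=(20.0, 40.0, 60.0, 80.0), higher_is_worse=True),
        "ozone_yl": ClassMap(breakpoints=(5.0, 10.0, 16.0, 22.0), higher_is_worse=True),
    }


@dataclass
class ScoreMap:
    """Per-layer integer scores and their composite sum."""

    grid: GridSpec
    scores: dict[str, np.ndarray]  # name -> int scores, 0 = missing
    composite: np.ndarray  # float; NaN where any layer missing

    @property
    def n_layers(self) -> int:
        return len(self.scores)


def score_layer(layer: StressLayer, class_map: ClassMap | None = None) -> np.ndarray:
    """Score one layer; returns an integer array with 0 marking missing cells."""
    if class_map is None:
        class_map = default_class_maps()[layer.name]
    fld = layer.field
    out = np.zeros(fld.grid.shape, dtype=int)
    ok = ~fld.missing
    if class_map.category_scores is not None:
        if not fld.is_categorical:
            raise ValueError(f"layer {layer.name!r}: category scores on a continuous field")
        table = class_map.category_scores
        uncovered = set(np.unique(fld.values[ok]).tolist()) - set(table)
        if uncovered:
            raise ValueError(f"layer {layer.name!r}: unscored class(es) {sorted(uncovered)}")
        for cat, s in table.items():
            out[ok & (fld.values == cat)] = int(s)
    else:
        if fld.is_categorical:
            raise ValueError(f"layer {layer.name!r}: breakpoints on a categorical field")
        vals = fld.values.astype(float)
        bins = np.digitize(vals, class_map.breakpoints, right=False) + 1  # 1..5
        if not class_map.higher_is_worse:
            bins = 6 - bins
        out[ok] = bins[ok]
    return out


def flood_layer_from_districts(
    districts: dict[str, BaseGeometry],
    counts: dict[str, float],
    grid: GridSpec,
) -> StressLayer:
    """Rasterise district flood-occurrence counts by majority overlap area.

    Each cell takes the count of the district covering the greatest share of
    its footprint (the same majority rule used for sub-region assignment);
    cells outside every district are missing.
    """
    missing_counts = sorted(set(districts) - set(counts))
    if missing_counts:
        raise KeyError(f"no flood count for district(s): {missing_counts}")
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"negative flood count for {name!r}")
    rmap = assign_cells(grid, districts)
    if not rmap.assigned_mask().any():
        raise ValueError("districts do not overlap the grid anywhere")
    vals = np.full(grid.shape, np.nan)
    for name in districts:
        vals[rmap.cells_of(name)] = float(counts[name])
    fld = RasterField(grid, vals, units="floods")
    return StressLayer(name="flood", field=fld, source="district-majority")


def composite_score(
    layers: list[StressLayer],
    class_maps: dict[str, ClassMap] | None = None,
) -> ScoreMap:
    """Score every layer and sum into the composite crop-stress score.

    All layers must share one grid.  Cells missing in any layer are missing
    in the composite (per-layer missing counts are retained in the scores'
    zeros).
    """
    if not layers:
        raise ValueError("need at least one stress layer")
    names = [l.name for l in layers]
    if len(names) != len(set(names)):
        raise ValueError("duplicate layer names in scoring run")
    grid = layers[0].field.grid
    maps = default_class_maps()
    if class_maps:
        maps.update(class_maps)
    scores: dict[str, np.ndarray] = {}
    for layer in layers:
        if layer.field.grid != grid:
            raise ValueError(f"layer {layer.name!r} is on a different grid")
        scores[layer.name] = score_layer(layer, maps.get(layer.name))
    stack = np.stack(list(scores.values()))
    any_missing = (stack == 0).any(axis=0)
    composite = stack.sum(axis=0).astype(float)
    composite[any_missing] = np.nan
    return ScoreMap(grid=grid, scores=scores, composite=composite)
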