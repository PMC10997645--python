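"""1-5 stress scoring and the composite crop-stress score."""

import numpy as np
import pytest
from shapely.geometry import box

from ozoneyield.grid import GridSpec, RasterField
from ozoneyield.stress import (
    SOIL_CLASSES,
    ClassMap,
    StressLayer,
    composite_score,
    default_class_maps,
    flood_layer_from_districts,
    score_layer,
)

GRID = GridSpec(0, 0, 1, 1, 3, 2)


def continuous_layer(name, values):
    return StressLayer(name, RasterField(GRID, np.asarray(values, float)))


class TestScoreLayer:
    def test_best_soil_class_scores_one(self):
        vals = np.full(GRID.shape, SOIL_CLASSES[0], dtype=object)
        vals[0, 0] = SOIL_CLASSES[4]
        layer = StressLayer("soil_nutrient",
                            RasterField(GRID, vals, categories=SOIL_CLASSES))
        s = score_layer(layer)
        assert s[0, 0] == 5
        assert (s.ravel()[1:] == 1).all()

    def test_hot_temperature_scores_five(self):
        s = score_layer(continuous_layer("temperature", np.full(GRID.shape, 36.0)))
        assert (s == 5).all()

    @pytest.mark.parametrize("spei,expected", [
        (1.0, 1), (-0.2, 2), (-0.7, 3), (-1.2, 4), (-2.0, 5),
    ])
    def test_spei_dryness_ladder(self, spei, expected):
        s = score_layer(continuous_layer("spei", np.full(GRID.shape, spei)))
        assert (s == expected).all()

    def test_random_breakpoints_match_bruteforce(self, rng):
        vals = rng.uniform(0, 100, GRID.shape)
        bp = tuple(sorted(rng.uniform(0, 100, 4)))
        cm = ClassMap(breakpoints=bp, higher_is_worse=True)
        s = score_layer(continuous_layer("deprivation", vals), cm)
        for j in range(GRID.n_rows):
            for i in range(GRID.n_cols):
                expected = 1 + sum(vals[j, i] >= b for b in bp)
                assert s[j, i] == expected

    def test_orientation_flip(self, rng):
        vals = rng.uniform(-3, 3, GRID.shape)
        bp = (-1.5, -1.0, -0.5, 0.0)
        hi = score_layer(continuous_layer("spei", vals),
                         ClassMap(breakpoints=bp, higher_is_worse=True))
        lo = score_layer(continuous_layer("spei", vals),
                         ClassMap(breakpoints=bp, higher_is_worse=False))
        assert ((hi + lo) == 6).all()

    def test_missing_stays_missing(self):
        vals = np.full(GRID.shape, 30.0)
        vals[0, 0] = np.nan
        s = score_layer(continuous_layer("temperature", vals))
        assert s[0, 0] == 0 and (s.ravel()[1:] > 0).all()

    def test_uncovered_class_named(self):
        vals = np.full(GRID.shape, "Mystery class", dtype=object)
        layer = StressLayer(
            "soil_nutrient",
            RasterField(GRID, vals, categories=SOIL_CLASSES + ("Mystery class",)),
        )
        with pytest.raises(ValueError, match="Mystery class"):
            score_layer(layer, default_class_maps()["soil_nutrient"])


class TestFloodLayer:
    def test_cell_fully_inside_district(self):
        layer = flood_layer_from_districts(
            {"d1": box(-1, -1, 10, 10)}, {"d1": 3}, GRID)
        assert (layer.field.values == 3.0).all()

    def test_majority_straddle(self):
        g = GridSpec(0, 0, 1, 1, 1, 1)
        layer = flood_layer_from_districts(
            {"d1": box(0, 0, 0.6, 1), "d2": box(0.6, 0, 1, 1)},
            {"d1": 5, "d2": 0}, g)
        assert layer.field.values[0, 0] == 5.0

    def test_checkerboard_matches_intersection_oracle(self):
        districts = {f"d{i}{j}": box(i, j, i + 1, j + 1)
                     for i in range(3) for j in range(2)}
        counts = {name: float(k) for k, name in enumerate(districts)}
        layer = flood_layer_from_districts(districts, counts, GRID)
        for j in range(GRID.n_rows):
            for i in range(GRID.n_cols):
                cell = GRID.cell_box(j, i)
                best = max(districts, key=lambda n: cell.intersection(districts[n]).area)
                assert layer.field.values[j, i] == counts[best]

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            flood_layer_from_districts({"d": box(50, 50, 60, 60)}, {"d": 1}, GRID)


class TestComposite:
    def layers(self, scores):
        """One continuous layer per requested score, using deprivation bins."""
        # deprivation defaults: quintile breakpoints 20/40/60/80
        value_for_score = {1: 10.0, 2: 30.0, 3: 50.0, 4: 70.0, 5: 90.0}
        names = ["soil_nutrient", "spei", "flood", "temperature", "deprivation",
                 "ozone_yl"]
        cm = ClassMap(breakpoints=(20, 40, 60, 80), higher_is_worse=True)
        out, maps = [], {}
        for name, s in zip(names, scores):
            out.append(continuous_layer(name, np.full(GRID.shape, value_for_score[s])))
            maps[name] = cm
        return out, maps

    def test_minimum_composite(self):
        layers, maps = self.layers([1] * 6)
        assert (composite_score(layers, maps).composite == 6).all()

    def test_maximum_composite(self):
        layers, maps = self.layers([5] * 6)
        assert (composite_score(layers, maps).composite == 30).all()

    def test_sum_and_permutation_invariance(self, rng):
        scores = rng.integers(1, 6, size=6).tolist()
        layers, maps = self.layers(scores)
        c1 = composite_score(layers, maps).composite
        assert (c1 == sum(scores)).all()
        perm = [layers[i] for i in rng.permutation(6)]
        c2 = composite_score(perm, maps).composite
        np.testing.assert_array_equal(c1, c2)

    def test_missing_any_layer_missing_composite(self):
        layers, maps = self.layers([2, 2, 2, 2, 2, 2])
        vals = layers[0].field.values.copy()
        vals[0, 0] = np.nan
        layers[0] = continuous_layer("soil_nutrient", vals)
        comp = composite_score(layers, maps).composite
        assert np.isnan(comp[0, 0]) and np.isfinite(comp[1, 1])

    def test_duplicate_layer_rejected(self):
        layers, maps = self.layers([1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="duplicate"):
            composite_score([layers[0], layers[0]], maps)

    def test_grid_mismatch_rejected(self):
        other = GridSpec(0, 0, 1, 1, 2, 2)
        a = continuous_layer("spei", np.zeros(GRID.shape))
        b = StressLayer("temperature", RasterField(other, np.zeros((2, 2))))
        with pytest.raises(ValueError, match="grid"):
            composite_score([a, b])
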