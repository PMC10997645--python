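"""Spatial plumbing: cell assignment, regridding, zonal statistics."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from ozoneyield.grid import (
    GridSpec,
    RasterField,
    UNASSIGNED,
    assign_cells,
    regrid,
    zonal_stat,
)


class TestGridSpec:
    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, -1.0, 1.0, 2, 2)
        with pytest.raises(ValueError):
            GridSpec(0, 0, 1.0, 1.0, 0, 2)

    def test_edges_and_centers(self):
        g = GridSpec(10.0, -2.0, 0.5, 0.25, 4, 2)
        assert g.lon_edges().tolist() == [10.0, 10.5, 11.0, 11.5, 12.0]
        assert g.lat_centers().tolist() == [-1.875, -1.625]
        assert g.cell_area == pytest.approx(0.125)


class TestAssignCells:
    def test_containment(self):
        g = GridSpec(0, 0, 1, 1, 2, 2)
        rmap = assign_cells(g, {"only": box(-1, -1, 5, 5)})
        assert (rmap.cell_assignment == "only").all()

    def test_majority_straddle(self):
        # cell [0,1)x[0,1): A covers 70% (lon < 0.7), B the rest
        g = GridSpec(0, 0, 1, 1, 1, 1)
        rmap = assign_cells(g, {"A": box(0, 0, 0.7, 1), "B": box(0.7, 0, 1, 1)})
        assert rmap.cell_assignment[0, 0] == "A"

    def test_midline_split_matches_bruteforce(self, unit_grid_4x4):
        polys = {"A": box(0, 0, 2, 4), "B": box(2, 0, 4, 4)}
        rmap = assign_cells(unit_grid_4x4, polys)
        # brute-force per-cell intersection areas
        for j in range(4):
            for i in range(4):
                cell = unit_grid_4x4.cell_box(j, i)
                areas = {n: cell.intersection(p).area for n, p in polys.items()}
                expected = max(areas, key=areas.get)
                assert rmap.cell_assignment[j, i] == expected
        assert (rmap.cell_assignment[:, :2] == "A").all()
        assert (rmap.cell_assignment[:, 2:] == "B").all()

    def test_no_overlap_cells_unassigned(self):
        g = GridSpec(0, 0, 1, 1, 2, 1)
        rmap = assign_cells(g, {"A": box(0, 0, 1, 1)})
        assert rmap.cell_assignment[0, 0] == "A"
        assert rmap.cell_assignment[0, 1] == UNASSIGNED

    def test_empty_and_degenerate_polygons_rejected(self, unit_grid_4x4):
        with pytest.raises(ValueError, match="empty"):
            assign_cells(unit_grid_4x4, {})
        with pytest.raises(ValueError, match="flatland"):
            assign_cells(
                unit_grid_4x4,
                {"flatland": Polygon([(0, 0), (1, 0), (2, 0)])},  # collinear, zero area
            )

    def test_idempotent(self, unit_grid_4x4):
        polys = {"A": box(0, 0, 2, 4), "B": box(2, 0, 4, 4)}
        a = assign_cells(unit_grid_4x4, polys).cell_assignment
        b = assign_cells(unit_grid_4x4, polys).cell_assignment
        assert (a == b).all()


class TestRegrid:
    def test_identity_any_method(self, unit_grid_4x4, rng):
        f = RasterField(unit_grid_4x4, rng.random(unit_grid_4x4.shape))
        for method in ("nearest", "area_weighted_mean", "sum_conserving"):
            out = regrid(f, unit_grid_4x4, method=method)
            np.testing.assert_allclose(out.values, f.values, rtol=1e-12)

    def test_area_weighted_mean_equal_areas(self):
        src = GridSpec(0, 0, 1, 1, 2, 2)
        tgt = GridSpec(0, 0, 2, 2, 1, 1)
        f = RasterField(src, np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = regrid(f, tgt, method="area_weighted_mean")
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_sum_conserving_total(self):
        src = GridSpec(0, 0, 1, 1, 2, 2)
        tgt = GridSpec(0, 0, 2, 2, 1, 1)
        f = RasterField(src, np.array([[10.0, 0.0], [0.0, 10.0]]), units="t")
        out = regrid(f, tgt, method="sum_conserving")
        assert out.values[0, 0] == pytest.approx(20.0)

    def test_sum_conserving_random_nested_grids(self, rng):
        # random rasters on a coarse grid, refined targets: totals must agree
        for _ in range(20):
            n = int(rng.integers(2, 6))
            src = GridSpec(0, 0, 1.0, 1.0, n, n)
            refine = int(rng.integers(2, 5))
            tgt = GridSpec(0, 0, 1.0 / refine, 1.0 / refine, n * refine, n * refine)
            f = RasterField(src, rng.random((n, n)) * 100)
            out = regrid(f, tgt, method="sum_conserving")
            assert out.values.sum() == pytest.approx(f.values.sum(), rel=1e-9)

    def test_nearest_takes_containing_cell(self):
        src = GridSpec(0, 0, 1, 1, 2, 1)
        tgt = GridSpec(0, 0, 0.5, 0.5, 4, 2)
        f = RasterField(src, np.array([[5.0, 9.0]]))
        out = regrid(f, tgt, method="nearest")
        np.testing.assert_array_equal(out.values[:, :2], 5.0)
        np.testing.assert_array_equal(out.values[:, 2:], 9.0)

    def test_majority_categorical(self):
        src = GridSpec(0, 0, 1, 1, 2, 2)
        vals = np.array([["a", "a"], ["a", "b"]], dtype=object)
        f = RasterField(src, vals, categories=("a", "b"))
        tgt = GridSpec(0, 0, 2, 2, 1, 1)
        out = regrid(f, tgt, method="majority")
        assert out.values[0, 0] == "a"

    def test_majority_on_continuous_rejected(self, unit_grid_4x4):
        f = RasterField(unit_grid_4x4, np.zeros(unit_grid_4x4.shape))
        with pytest.raises(ValueError, match="categorical"):
            regrid(f, unit_grid_4x4, method="majority")

    def test_disjoint_grids_rejected(self, unit_grid_4x4):
        f = RasterField(unit_grid_4x4, np.zeros(unit_grid_4x4.shape))
        far = GridSpec(100, 0, 1, 1, 2, 2)
        with pytest.raises(ValueError, match="disjoint"):
            regrid(f, far, method="nearest")

    def test_missing_source_cells_excluded_from_mean(self):
        src = GridSpec(0, 0, 1, 1, 2, 2)
        vals = np.array([[1.0, np.nan], [3.0, np.nan]])
        f = RasterField(src, vals)
        tgt = GridSpec(0, 0, 2, 2, 1, 1)
        out = regrid(f, tgt, method="area_weighted_mean")
        assert out.values[0, 0] == pytest.approx(2.0)


class TestZonalStat:
    def test_mean_and_sum(self, two_region_map, unit_grid_4x4):
        vals = np.full(unit_grid_4x4.shape, np.nan)
        vals[0, 0], vals[0, 1] = 10.0, 20.0
        f = RasterField(unit_grid_4x4, vals)
        t = zonal_stat(f, two_region_map, "mean")
        assert t.set_index("region").loc["A", "value"] == pytest.approx(15.0)
        t = zonal_stat(f, two_region_map, "sum")
        assert t.set_index("region").loc["A", "value"] == pytest.approx(30.0)

    def test_region_without_cells_is_missing_not_zero(self, two_region_map, unit_grid_4x4):
        vals = np.full(unit_grid_4x4.shape, np.nan)
        vals[0, 0] = 1.0
        t = zonal_stat(RasterField(unit_grid_4x4, vals), two_region_map, "mean")
        b = t.set_index("region").loc["B"]
        assert np.isnan(b["value"]) and b["n_cells"] == 0

    def test_masked_matches_bruteforce(self, two_region_map, unit_grid_4x4, rng):
        vals = rng.random(unit_grid_4x4.shape)
        prod = rng.random(unit_grid_4x4.shape) < 0.5
        f = RasterField(unit_grid_4x4, vals)
        mask = RasterField(unit_grid_4x4, prod.astype(float))
        t = zonal_stat(f, two_region_map, "mean", mask=mask).set_index("region")
        for name in ("A", "B"):
            sel = (two_region_map.cell_assignment == name) & prod
            if sel.any():
                assert t.loc[name, "value"] == pytest.approx(vals[sel].mean())

    def test_sum_over_all_regions_equals_global_sum(self, two_region_map, unit_grid_4x4, rng):
        vals = rng.random(unit_grid_4x4.shape)
        t = zonal_stat(RasterField(unit_grid_4x4, vals), two_region_map, "sum")
        assert t["value"].sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_grid_mismatch_rejected(self, two_region_map):
        other = GridSpec(0, 0, 1, 1, 3, 3)
        f = RasterField(other, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="grids"):
            zonal_stat(f, two_region_map, "mean")
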