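"""Production-loss arithmetic and the sub-region/national loss table."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from ozoneyield.dose_response import default_model
from ozoneyield.exposure import PODField, SeasonWindow
from ozoneyield.grid import GridSpec, assign_cells
from ozoneyield.loss import (
    NATIONAL_LABEL,
    aggregate_loss_table,
    production_loss,
    relative_yield,
    run_assessment,
)
from ozoneyield.production import ProductionRaster
from ozoneyield.reference import uganda_production_losses_2015


class TestRelativeYield:
    @pytest.mark.parametrize("yl,expected", [(0.0, 1.0), (20.0, 0.8), (50.0, 0.5)])
    def test_values(self, yl, expected):
        assert relative_yield(yl) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relative_yield(-1.0)
        with pytest.raises(ValueError):
            relative_yield(100.0)

    def test_literal_form_is_reciprocal(self):
        assert relative_yield(50.0, literal_eq2=True) == pytest.approx(2.0)


class TestProductionLoss:
    @pytest.mark.parametrize(
        "p,yl,expected", [(100, 0, 0), (100, 20, 25), (80, 50, 80), (0, 30, 0)]
    )
    def test_values(self, p, yl, expected):
        assert production_loss(p, yl) == pytest.approx(expected)

    def test_closed_form_identity_grid(self):
        P, YL = np.meshgrid(np.linspace(0, 1000, 21), np.linspace(0, 99, 34))
        loss = production_loss(P, YL)
        np.testing.assert_allclose(loss, P * YL / (100 - YL), rtol=1e-12)
        # loss as a fraction of pre-loss potential equals the yield-loss fraction
        with np.errstate(invalid="ignore"):
            frac = np.where(P > 0, loss / (P + loss), np.nan)
        np.testing.assert_allclose(frac[P > 0], YL[P > 0] / 100.0, atol=1e-12)

    def test_negative_production_rejected(self):
        with pytest.raises(ValueError):
            production_loss(-1.0, 10.0)


def two_region_setup(pod_by_region, prod_by_region, split=None):
    """Per-region constant POD and production on a 4x4 grid, one season."""
    grid = GridSpec(0, 0, 1, 1, 4, 4)
    regions = assign_cells(grid, {"A": box(0, 0, 2, 4), "B": box(2, 0, 4, 4)})
    pod_vals = np.zeros(grid.shape)
    prod_vals = np.zeros(grid.shape)
    for name in ("A", "B"):
        sel = regions.cells_of(name)
        pod_vals[sel] = pod_by_region[name]
        prod_vals[sel] = prod_by_region[name]
    pod = PODField(grid, SeasonWindow("season1", 91, 180), pod_vals)
    prod = ProductionRaster(grid=grid, values=prod_vals, season="season1")
    return regions, pod, prod


class TestRunAssessment:
    def test_uniform_10pct_loss(self):
        # POD chosen so the default slope gives exactly 10% loss;
        # 1000 t in a season -> loss 1000*10/90
        pod10 = 10.0 / 1.175
        regions, pod, prod = two_region_setup(
            {"A": pod10, "B": pod10}, {"A": 1000.0 / 8, "B": 0.0})
        res = run_assessment({"season1": pod}, default_model(), {"season1": prod},
                             regions)
        t = res.table.set_index(["sub_region", "season"])
        assert t.loc[("A", "season1"), "production_loss_t"] == pytest.approx(1000 * 10 / 90)
        assert t.loc[("A", "season1"), "mean_yield_loss_pct"] == pytest.approx(10.0)

    def test_zero_pod_all_zero(self):
        regions, pod, prod = two_region_setup({"A": 0, "B": 0}, {"A": 5, "B": 7})
        res = run_assessment({"season1": pod}, default_model(), {"season1": prod},
                             regions)
        assert (res.table["production_loss_t"] == 0).all()
        assert (res.table["mean_yield_loss_pct"] == 0).all()

    def test_two_region_closed_form(self):
        regions, pod, prod = two_region_setup({"A": 8.0, "B": 16.0},
                                              {"A": 50.0, "B": 20.0})
        res = run_assessment({"season1": pod}, default_model(), {"season1": prod},
                             regions)
        t = res.table.set_index(["sub_region", "season"])
        for name, pod_v, prod_v in (("A", 8.0, 50.0), ("B", 16.0, 20.0)):
            yl = 1.175 * pod_v
            cells = 8  # cells per region
            expected = cells * prod_v * yl / (100 - yl)
            assert t.loc[(name, "season1"), "production_loss_t"] == pytest.approx(expected, rel=1e-12)
        # national row aggregates at cell level
        nat = t.loc[(NATIONAL_LABEL, "season1")]
        assert nat["production_loss_t"] == pytest.approx(
            t.loc[("A", "season1"), "production_loss_t"]
            + t.loc[("B", "season1"), "production_loss_t"], rel=1e-12)
        assert nat["mean_yield_loss_pct"] == pytest.approx(
            (1.175 * 8 + 1.175 * 16) / 2)

    def test_zero_production_cells_count_in_mean_not_in_loss(self):
        regions, pod, prod = two_region_setup({"A": 10.0, "B": 10.0},
                                              {"A": 100.0, "B": 0.0})
        res = run_assessment({"season1": pod}, default_model(), {"season1": prod},
                             regions)
        t = res.table.set_index(["sub_region", "season"])
        assert t.loc[("B", "season1"), "production_loss_t"] == 0.0
        assert t.loc[("B", "season1"), "mean_yield_loss_pct"] == pytest.approx(11.75)

    def test_monotone_in_pod(self):
        regions, pod, prod = two_region_setup({"A": 5.0, "B": 5.0},
                                              {"A": 10.0, "B": 10.0})
        res_lo = run_assessment({"season1": pod}, default_model(),
                                {"season1": prod}, regions)
        pod_hi = PODField(pod.grid, pod.window, pod.values + 1.0)
        res_hi = run_assessment({"season1": pod_hi}, default_model(),
                                {"season1": prod}, regions)
        assert (res_hi.table["production_loss_t"].to_numpy()
                >= res_lo.table["production_loss_t"].to_numpy()).all()

    def test_label_mismatch_rejected(self):
        regions, pod, prod = two_region_setup({"A": 5, "B": 5}, {"A": 1, "B": 1})
        with pytest.raises(ValueError, match="season"):
            run_assessment({"season2": pod}, default_model(), {"season2": prod},
                           regions)


class TestAggregateLossTable:
    def test_row_and_national_totals(self):
        df = pd.DataFrame({
            "sub_region": ["A", "B", "C"],
            "season1": [10.0, 20.0, 5.0],
            "season2": [1.0, 2.0, np.nan],  # C unimodal
        })
        out = aggregate_loss_table(df).set_index("sub_region")
        assert out.loc["C", "total"] == 5.0
        assert out.loc[NATIONAL_LABEL, "season1"] == 35.0
        assert out.loc[NATIONAL_LABEL, "season2"] == 3.0
        assert out.loc[NATIONAL_LABEL, "total"] == 38.0

    def test_published_reference_totals(self):
        """Re-aggregating the published per-sub-region cells reproduces the
        published national totals (season 1 within the 1 t rounding of the
        printed column)."""
        ref = uganda_production_losses_2015()
        out = aggregate_loss_table(ref).set_index("sub_region")
        assert out.loc[NATIONAL_LABEL, "season2"] == 70137
        assert abs(out.loc[NATIONAL_LABEL, "season1"] - 114355) <= 1
        assert round(out.loc[NATIONAL_LABEL, "total"] / 1000) == 184
        assert out.loc["North Buganda", "total"] == 15837
        assert out.loc["Acholi", "total"] == 34052
        assert out.loc["Ankole", "total"] == 30902
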