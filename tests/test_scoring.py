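"""Field-based iTIL scoring: compartments, grids, densities, flags, summaries."""

import math

import numpy as np
import pytest

from itilscore.geometry import LabelRaster
from itilscore.points import PointSet
from itilscore.scoring import (Field, FlagCriteria, ScoringConfig, SlideScore,
                               ai_itil_score, assign_compartment, build_field_grid,
                               classify, flag_slide, hpf_equivalent_density,
                               manual_score_classify, score_field, score_slide,
                               snapped_field_side_um, summarize_cohort)

TSN = {"other": 0, "tumour": 1, "stroma": 2, "necrosis": 3}
CFG = ScoringConfig()


def _mask(grid, mpp=0.5):
    return LabelRaster(np.asarray(grid, dtype=np.uint8), mpp, dict(TSN))


def test_field_side_matches_hpf_area():
    # square of side (d/2)*sqrt(pi) has exactly the circular HPF area
    assert CFG.field_area_mm2 == pytest.approx(math.pi * 0.275 ** 2, abs=1e-9)
    assert CFG.field_side_um == pytest.approx(487.4254, abs=1e-3)
    assert snapped_field_side_um(CFG, 0.5) == pytest.approx(487.5)


class TestAssignCompartment:
    def test_lookup_labels(self):
        grid = np.zeros((20, 20), np.uint8)
        grid[:10] = TSN["tumour"]
        grid[10:] = TSN["necrosis"]
        m = _mask(grid, mpp=1.0)
        pts = PointSet(np.array([[5.0, 2.0], [5.0, 15.0], [50.0, 50.0]]))
        out = assign_compartment(pts, m)
        assert list(out.compartment) == ["tumour", "necrosis", "unassigned"]

    def test_matches_bruteforce_lookup(self, rng):
        grid = rng.integers(0, 4, size=(64, 64)).astype(np.uint8)
        m = _mask(grid, mpp=0.5)
        pts = PointSet(rng.uniform(0, 32, (1000, 2)))
        out = assign_compartment(pts, m)
        inv = {v: k for k, v in TSN.items()}
        for (x, y), lab in zip(pts.xy_um, out.compartment):
            expect = inv[int(grid[int(y // 0.5), int(x // 0.5)])]
            expect = "unassigned" if expect == "other" else expect
            assert lab == expect


class TestFieldGrid:
    def test_single_field_for_one_field_sized_bbox(self):
        grid = np.zeros((1000, 1000), np.uint8)
        grid[10:985, 5:980] = TSN["tumour"]  # 975 px ~ 487.5 um at 0.5 MPP
        fields = build_field_grid(_mask(grid), CFG)
        assert len(fields) == 1

    def test_two_by_two(self):
        grid = np.zeros((2000, 2000), np.uint8)
        grid[0:1950, 0:1950] = TSN["tumour"]
        assert len(build_field_grid(_mask(grid), CFG)) == 4

    def test_empty_mask_empty_grid(self):
        assert build_field_grid(_mask(np.zeros((64, 64))), CFG) == []


def _empty_points():
    return PointSet.empty().with_compartment(np.array([], dtype=object))


class TestScoreField:
    def test_full_tumour_field_density(self):
        side_px = 975
        grid = np.full((side_px, side_px), TSN["tumour"], np.uint8)
        m = _mask(grid)
        xy = np.tile([[100.0, 100.0]], (10, 1)) + np.arange(10)[:, None] * 5
        pts = PointSet(xy).with_compartment(np.array(["tumour"] * 10, object))
        f = score_field((0.0, 0.0, 487.5), m, pts, CFG)
        assert f.tumour_area_mm2 == pytest.approx(0.23766, abs=2e-4)
        assert f.itil_count == 10
        assert f.density == pytest.approx(10 / f.tumour_area_mm2)
        assert f.density == pytest.approx(42.09, abs=0.15)

    def test_low_tumour_fraction_ineligible(self):
        grid = np.zeros((975, 975), np.uint8)
        grid[:97, :488] = TSN["tumour"]  # ~5% of the field
        f = score_field((0.0, 0.0, 487.5), _mask(grid), _empty_points(), CFG)
        assert not f.eligible

    def test_ten_percent_tumour_is_eligible(self):
        grid = np.zeros((975, 975), np.uint8)
        grid[:195, :488] = TSN["tumour"]  # > 10%
        f = score_field((0.0, 0.0, 487.5), _mask(grid), _empty_points(), CFG)
        assert f.eligible

    def test_zero_itils_zero_density(self):
        grid = np.full((975, 975), TSN["tumour"], np.uint8)
        f = score_field((0.0, 0.0, 487.5), _mask(grid), _empty_points(), CFG)
        assert f.density == 0.0 and f.eligible

    def test_matches_bruteforce_oracle(self, rng):
        """Pixel/point loop oracle over random fixtures, random offsets."""
        for _ in range(30):
            grid = (rng.random((80, 80)) < 0.4).astype(np.uint8)
            m = _mask(grid, mpp=1.0)
            n = int(rng.integers(0, 40))
            pts = PointSet(rng.uniform(0, 80, (n, 2))).with_compartment(
                rng.choice(["tumour", "stroma"], size=n).astype(object))
            x0, y0 = rng.uniform(-10, 60, 2)
            side = float(rng.uniform(10, 40))
            f = score_field((x0, y0, side), m, pts, CFG)
            # oracle: explicit loops over pixels and points
            t_px = 0
            for r in range(80):
                for c in range(80):
                    if grid[r, c] == 1 and x0 <= c * 1.0 < x0 + side and y0 <= r * 1.0 < y0 + side:
                        t_px += 1
            count = sum(1 for (x, y), comp in zip(pts.xy_um, pts.compartment)
                        if comp == "tumour" and x0 <= x < x0 + side and y0 <= y < y0 + side)
            assert f.tumour_area_mm2 == pytest.approx(t_px * 1e-6)
            assert f.itil_count == count


def test_grid_conservation_no_double_counting(rng):
    """Sum of L_i over the grid equals the number of tumour points in the
    grid-covered region: half-open fields tile the plane."""
    grid = (rng.random((700, 700)) < 0.5).astype(np.uint8)
    m = _mask(grid, mpp=1.0)
    n = 400
    pts = PointSet(rng.uniform(0, 700, (n, 2))).with_compartment(
        np.array(["tumour"] * n, dtype=object))
    fields = build_field_grid(m, CFG)
    total = sum(score_field(b, m, pts, CFG).itil_count for b in fields)
    x0, y0, _ = fields[0]
    nx = max(f[0] for f in fields) + fields[0][2]
    ny = max(f[1] for f in fields) + fields[0][2]
    inside = ((pts.xy_um[:, 0] >= x0) & (pts.xy_um[:, 0] < nx)
              & (pts.xy_um[:, 1] >= y0) & (pts.xy_um[:, 1] < ny))
    assert total == int(inside.sum())


class TestPatientScore:
    def _slide(self, densities):
        # tumour area 1.0 mm^2 per field so density == count
        fields = [Field(i, 0, 0, 487.5, 1.0, int(d), True) for i, d in enumerate(densities)]
        return SlideScore("s", fields)

    def test_odd_median(self):
        p = ai_itil_score([self._slide([10, 20, 30])], CFG)
        assert p.ai_itil_score == 20

    def test_even_median_is_mean_of_central_pair(self):
        p = ai_itil_score([self._slide([10, 20])], CFG)
        assert p.ai_itil_score == 15

    def test_pooling_across_slides_equals_single_pool(self):
        a = ai_itil_score([self._slide([10, 20, 30, 40])], CFG)
        b = ai_itil_score([self._slide([30, 10]), self._slide([40, 20])], CFG)
        assert a.ai_itil_score == b.ai_itil_score

    def test_zero_eligible_fields_flagged_no_class(self):
        empty = SlideScore("s", [Field(0, 0, 0, 487.5, 0.0, 0, False)])
        p = ai_itil_score([empty], CFG)
        assert p.ai_itil_score is None and p.til_class is None and p.flagged

    def test_monotone_in_added_itils(self):
        lo = ai_itil_score([self._slide([10, 20, 30])], CFG)
        hi = ai_itil_score([self._slide([10, 21, 30])], CFG)
        assert hi.ai_itil_score >= lo.ai_itil_score


class TestClassify:
    @pytest.mark.parametrize("score, expected", [
        (17.0, "TIL-High"), (16.9, "TIL-Low"), (42.09, "TIL-High"), (0.0, "TIL-Low"),
    ])
    def test_boundary_convention(self, score, expected):
        assert classify(score, 17.0) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), 17.0)


class TestHPFEquivalence:
    def test_half_tumour_hpf_gives_17(self):
        assert round(hpf_equivalent_density(2, 0.5, 0.55)) == 17

    def test_manual_range_14_to_21(self):
        assert round(hpf_equivalent_density(2, 0.6, 0.55)) == 14
        assert round(hpf_equivalent_density(2, 0.4, 0.55)) == 21

    def test_zero_tils_zero_density(self):
        assert hpf_equivalent_density(0, 0.3, 0.55) == 0.0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            hpf_equivalent_density(2, 0.0, 0.55)


class TestManualScore:
    @pytest.mark.parametrize("counts, expected", [
        ((2, 2, 2, 2, 2), "TIL-High"),
        ((1, 1, 1, 1, 1), "TIL-Low"),
        ((0, 0, 0, 5, 5), "TIL-High"),  # mean exactly 2
    ])
    def test_mean_rule(self, counts, expected):
        assert manual_score_classify(counts, CFG) == expected

    def test_empty_and_wrong_length(self):
        with pytest.raises(ValueError):
            manual_score_classify([], CFG)
        with pytest.raises(ValueError):
            manual_score_classify([1, 2], CFG)


class TestFlags:
    def test_insufficient_tumour(self):
        rep = flag_slide({"tumour_area_mm2": 0.2}, FlagCriteria())
        assert rep.flagged
        assert rep.criteria_triggered[0][0] == "insufficient-tumour"

    def test_too_few_fields(self):
        rep = flag_slide({"eligible_field_count": 3}, FlagCriteria())
        assert [c[0] for c in rep.criteria_triggered] == ["too-few-fields"]

    def test_all_clear(self):
        rep = flag_slide({"tumour_area_mm2": 5.0, "eligible_field_count": 30,
                          "cancer_fraction_of_tissue": 0.4, "stain_failures": 0},
                         FlagCriteria())
        assert not rep.flagged

    def test_stain_failure_flags(self):
        rep = flag_slide({"stain_failures": 2}, FlagCriteria())
        assert rep.criteria_triggered[0][0] == "stain-normalisation-failure"


class TestCohortSummary:
    @pytest.mark.parametrize("flagged, total, pct", [
        (38, 1108, 3.4), (53, 938, 5.7), (35, 388, 9.0), (0, 100, 0.0),
    ])
    def test_flag_rates(self, flagged, total, pct):
        import pandas as pd
        df = pd.DataFrame({
            "flagged": [True] * flagged + [False] * (total - flagged),
            "til_class": ["TIL-High"] * total,
            "ai_itil_score": [20.0] * total,
        })
        assert summarize_cohort(df)["flag_rate_pct"] == pct

    def test_empty_cohort_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())


def test_score_slide_end_to_end(small_layout, small_points):
    score = score_slide("s1", small_layout.tsn, small_points, CFG)
    assert score.eligible_count > 0
    assert np.isfinite(score.median_density)
    table = score.field_table()
    assert set(table.columns) >= {"field_index", "T_i_mm2", "L_i", "density", "eligible"}
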