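"""Heatmap codec: Gaussian encoding, blob decoding, point NMS, tile merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from itilscore.geometry import plan_tiles
from itilscore.points import (DetectionConfig, HeatmapSpec, PointSet, decode_heatmap,
                              encode_points, merge_tile_detections, point_nms)


def nms_oracle(points: PointSet, radius: float) -> list[int]:
    """Quadratic greedy suppression, written independently of the kd-tree path."""
    idx = sorted(range(len(points)),
                 key=lambda i: (-points.confidence[i], points.xy_um[i, 1], points.xy_um[i, 0]))
    kept: list[int] = []
    for i in idx:
        ok = True
        for j in kept:
            dx = points.xy_um[i, 0] - points.xy_um[j, 0]
            dy = points.xy_um[i, 1] - points.xy_um[j, 1]
            if (dx * dx + dy * dy) ** 0.5 <= radius:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


class TestEncode:
    def test_empty_point_set_gives_zero_heatmap(self):
        h = encode_points(PointSet.empty(), (16, 16), HeatmapSpec(2.0, mpp=1.0))
        assert h.shape == (16, 16) and not h.any()

    def test_gaussian_profile(self):
        # point at the centre of pixel (10, 10), sigma = 2 px
        spec = HeatmapSpec(sigma_um=2.0, mpp=1.0)
        h = encode_points(PointSet(np.array([[10.5, 10.5]])), (32, 32), spec)
        assert h[10, 10] == pytest.approx(1.0)
        assert h[10, 12] == pytest.approx(np.exp(-0.5))
        assert h[12, 10] == pytest.approx(np.exp(-0.5))

    def test_coincident_points_combine_by_max(self):
        spec = HeatmapSpec(2.0, mpp=1.0)
        one = encode_points(PointSet(np.array([[8.5, 8.5]])), (16, 16), spec)
        two = encode_points(PointSet(np.array([[8.5, 8.5], [8.5, 8.5]])), (16, 16), spec)
        np.testing.assert_array_equal(one, two)

    def test_values_clipped_to_unit_interval(self):
        spec = HeatmapSpec(3.0, mpp=1.0)
        pts = PointSet(np.array([[10.5, 10.5], [12.5, 10.5], [11.5, 11.5]]))
        h = encode_points(pts, (24, 24), spec)
        assert 0.0 <= h.min() and h.max() <= 1.0


class TestDecode:
    def test_single_peak(self):
        spec = HeatmapSpec(2.0, mpp=1.0)
        h = 0.9 * encode_points(PointSet(np.array([[10.5, 10.5]])), (32, 32), spec)
        out = decode_heatmap(h, DetectionConfig(0.35, 2.0, 2.0), 1.0)
        assert len(out) == 1
        assert out.confidence[0] == pytest.approx(0.9)
        np.testing.assert_allclose(out.xy_um[0], [10.5, 10.5])

    def test_peak_below_confidence_gate_rejected(self):
        spec = HeatmapSpec(2.0, mpp=1.0)
        h = 0.30 * encode_points(PointSet(np.array([[10.5, 10.5]])), (32, 32), spec)
        assert len(decode_heatmap(h, DetectionConfig(0.35, 2.0, 2.0), 1.0)) == 0

    def test_all_zero_heatmap_decodes_empty(self):
        assert len(decode_heatmap(np.zeros((8, 8)), DetectionConfig(0.35, 2.0, 2.0), 1.0)) == 0

    def test_two_separated_peaks_recovered(self):
        spec = HeatmapSpec(2.0, mpp=1.0)
        planted = np.array([[10.5, 10.5], [20.5, 10.5]])
        h = encode_points(PointSet(planted), (40, 40), spec)
        out = decode_heatmap(h, DetectionConfig(0.35, 4.0, 4.0), 1.0)
        assert len(out) == 2
        d = np.linalg.norm(np.sort(out.xy_um, axis=0) - np.sort(planted, axis=0), axis=1)
        assert d.max() <= 1.0  # within one pixel

    def test_threshold_monotonicity(self, rng):
        spec = HeatmapSpec(2.0, mpp=1.0)
        pts = PointSet(rng.uniform(5, 120, (25, 2)))
        h = encode_points(pts, (128, 128), spec) * rng.uniform(0.3, 1.0)
        counts = [len(decode_heatmap(h, DetectionConfig(t, 2.0, 2.0), 1.0))
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestPointNMS:
    def test_close_pair_keeps_higher_confidence(self):
        p = PointSet(np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.9, 0.8]))
        out = point_nms(p, 4.0)
        assert len(out) == 1 and out.confidence[0] == 0.9

    def test_distant_pair_both_survive(self):
        p = PointSet(np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([0.9, 0.8]))
        assert len(point_nms(p, 4.0)) == 2

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 40))
            p = PointSet(rng.uniform(0, 50, (n, 2)), rng.random(n))
            out = point_nms(p, 5.0)
            kept = nms_oracle(p, 5.0)
            np.testing.assert_array_equal(out.xy_um, p.xy_um[kept])

    def test_idempotent_and_separated(self, rng):
        p = PointSet(rng.uniform(0, 30, (60, 2)), rng.random(60))
        once = point_nms(p, 3.0)
        twice = point_nms(once, 3.0)
        np.testing.assert_array_equal(once.xy_um, twice.xy_um)
        if len(once) > 1:
            d = np.linalg.norm(once.xy_um[:, None] - once.xy_um[None], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 3.0

    def test_requires_finite_confidence(self):
        p = PointSet(np.array([[0.0, 0.0]]), np.array([0.5]))
        object.__setattr__(p, "confidence", np.array([np.nan]))  # bypass validation
        with pytest.raises(ValueError):
            point_nms(p, 1.0)


@given(st.lists(st.tuples(st.floats(0, 50), st.floats(0, 50), st.floats(0, 1)),
                max_size=30))
def test_nms_oracle_property(items):
    xy = np.array([(x, y) for x, y, _ in items]).reshape(-1, 2)
    conf = np.array([c for *_, c in items])
    p = PointSet(xy, conf)
    out = point_nms(p, 4.0)
    kept = nms_oracle(p, 4.0)
    np.testing.assert_array_equal(out.xy_um, p.xy_um[kept])


class TestMergeTileDetections:
    def test_duplicate_across_overlap_counted_once(self):
        plan = plan_tiles((96, 64), 64, 32, 0.5)
        t0, t1 = plan.tiles
        # the same TIL at global pixel (40, 10) seen by both tiles
        per_tile = [(t0, PointSet(np.array([[40.0, 10.0]]), np.array([0.8]))),
                    (t1, PointSet(np.array([[8.0, 10.0]]), np.array([0.8])))]
        out = merge_tile_detections(per_tile, plan, DetectionConfig(0.35, 2.0, 2.0))
        assert len(out) == 1
        np.testing.assert_allclose(out.xy_um[0], [20.0, 5.0])

    def test_interior_detections_preserved(self):
        plan = plan_tiles((128, 64), 64, 0, 1.0)
        per_tile = [(t, PointSet(np.array([[10.0 + t.index, 20.0]]), np.array([0.9])))
                    for t in plan]
        out = merge_tile_detections(per_tile, plan, DetectionConfig(0.35, 2.0, 2.0))
        assert len(out) == len(plan.tiles)

    def test_foreign_tile_rejected(self):
        plan = plan_tiles((64, 64), 64, 0, 1.0)
        other = plan_tiles((128, 128), 64, 0, 1.0).tiles[3]
        with pytest.raises(ValueError, match="not part of the plan"):
            merge_tile_detections([(other, PointSet.empty())], plan,
                                  DetectionConfig(0.35, 2.0, 2.0))


def test_encode_decode_recovery_randomised(rng):
    """decode(encode(P)) recovers every point within 1 px when the planted
    separation exceeds max(2 * min_separation, 4 sigma)."""
    spec = HeatmapSpec(sigma_um=2.0, mpp=1.0)
    config = DetectionConfig(0.35, 4.0, 4.0)
    min_planted = max(2 * config.min_separation_um, 4 * spec.sigma_um) + 0.5
    for _ in range(25):
        raw = rng.uniform(10, 240, (30, 2))
        kept = []
        for q in raw:
            if all(np.hypot(*(q - k)) > min_planted for k in kept):
                kept.append(q)
        planted = np.array(kept)
        h = encode_points(PointSet(planted), (256, 256), spec)
        out = decode_heatmap(h, config, spec.mpp)
        assert len(out) == len(planted)
        d = np.linalg.norm(out.xy_um[:, None] - planted[None], axis=2).min(axis=1)
        assert d.max() <= 1.0
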