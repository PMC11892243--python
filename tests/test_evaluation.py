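"""Distance-matched detection metrics and segmentation Dice/F1."""

import numpy as np
import pytest

from itilscore.evaluation import (EvalConfig, average_precision, confidence_sweep,
                                  match_points, segmentation_f1)
from itilscore.geometry import LabelRaster
from itilscore.points import PointSet

CFG = EvalConfig(match_radius_um=4.0)


def _pts(coords, conf=None):
    coords = np.asarray(coords, float).reshape(-1, 2)
    return PointSet(coords, None if conf is None else np.asarray(conf, float))


class TestMatchPoints:
    def test_within_radius_is_tp(self):
        res = match_points(_pts([[3.0, 0.0]]), _pts([[0.0, 0.0]]), CFG)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_beyond_radius_is_fp_and_fn(self):
        res = match_points(_pts([[5.0, 0.0]]), _pts([[0.0, 0.0]]), CFG)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_identical_sets_perfect(self, rng):
        xy = rng.uniform(0, 100, (20, 2))
        res = match_points(_pts(xy), _pts(xy), CFG)
        assert res.precision == res.recall == res.f1 == 1.0

    def test_one_to_one_matching(self):
        # two predictions near one ground truth: only one may match
        res = match_points(_pts([[1.0, 0.0], [2.0, 0.0]], [0.9, 0.8]),
                           _pts([[0.0, 0.0]]), CFG)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.pairs[0][0] == 0  # the higher-confidence prediction matched

    def test_counts_partition_sets(self, rng):
        pred = _pts(rng.uniform(0, 60, (25, 2)), rng.random(25))
        gt = _pts(rng.uniform(0, 60, (18, 2)))
        res = match_points(pred, gt, CFG)
        assert res.tp + res.fp == 25 and res.tp + res.fn == 18

    def test_empty_conventions(self):
        both = match_points(PointSet.empty(), PointSet.empty(), CFG)
        assert both.precision == both.recall == both.f1 == 1.0
        none_pred = match_points(PointSet.empty(), _pts([[0, 0]]), CFG)
        assert none_pred.precision == none_pred.recall == none_pred.f1 == 0.0

    def test_greedy_equals_optimal_on_unambiguous_instances(self, rng):
        # each prediction within radius of exactly one ground truth
        gt = np.array([[i * 20.0, 0.0] for i in range(10)])
        pred = gt + rng.uniform(-2, 2, gt.shape)
        greedy = match_points(_pts(pred, rng.random(10)), _pts(gt), CFG)
        optimal = match_points(_pts(pred, rng.random(10)), _pts(gt),
                               EvalConfig(4.0, "optimal"))
        assert greedy.tp == optimal.tp == 10

    def test_optimal_beats_greedy_on_contested_instance(self):
        # one gt contested: greedy takes the nearer one and strands the other
        gt = _pts([[0.0, 0.0], [3.0, 0.0]])
        pred = _pts([[1.0, 0.0], [-3.0, 0.0]], [0.9, 0.8])
        greedy = match_points(pred, gt, CFG)
        optimal = match_points(pred, gt, EvalConfig(4.0, "optimal"))
        assert optimal.tp >= greedy.tp


class TestAveragePrecision:
    def test_perfect_detector(self, rng):
        xy = rng.uniform(0, 50, (12, 2))
        assert average_precision(_pts(xy, np.ones(12)), _pts(xy), CFG) == 1.0

    def test_all_misses(self):
        assert average_precision(_pts([[100.0, 100.0]], [0.9]), _pts([[0.0, 0.0]]), CFG) == 0.0

    def test_hand_enumerated_fixture(self):
        """10 TPs at staggered confidences plus 2 FPs at 0.85 and 0.45."""
        gt = np.array([[i * 20.0, 0.0] for i in range(10)])
        tp_conf = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        pred = np.vstack([gt, [[500.0, 0.0], [520.0, 0.0]]])
        conf = np.concatenate([tp_conf, [0.85, 0.45]])
        # hand enumeration: precision at each recall increment
        expected = sum([
            0.1 * 1.0,        # conf 1.0  -> 1/1
            0.1 * 1.0,        # conf 0.9  -> 2/2
            0.1 * (3 / 4),    # conf 0.8  -> 3 TP / (3 TP + 1 FP at 0.85)
            0.1 * (4 / 5),
            0.1 * (5 / 6),
            0.1 * (6 / 7),
            0.1 * (7 / 9),    # second FP (0.45) now included
            0.1 * (8 / 10),
            0.1 * (9 / 11),
            0.1 * (10 / 12),
        ])
        got = average_precision(_pts(pred, conf), _pts(gt), CFG)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bounds(self, rng):
        pred = _pts(rng.uniform(0, 40, (15, 2)), rng.random(15))
        gt = _pts(rng.uniform(0, 40, (12, 2)))
        assert 0.0 <= average_precision(pred, gt, CFG) <= 1.0


class TestSegmentationF1:
    C = {"bg": 0, "tumour": 1}

    def _m(self, grid):
        return LabelRaster(np.asarray(grid, np.uint8), 0.5, dict(self.C))

    def test_identical_masks(self):
        g = np.zeros((10, 10)); g[2:6, 2:6] = 1
        assert segmentation_f1(self._m(g), self._m(g), "tumour") == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10)); a[:2] = 1
        b = np.zeros((10, 10)); b[5:] = 1
        assert segmentation_f1(self._m(a), self._m(b), "tumour") == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10)); a[:, 0:4] = 1
        b = np.zeros((10, 10)); b[:, 2:6] = 1
        assert segmentation_f1(self._m(a), self._m(b), "tumour") == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = self._m(rng.integers(0, 2, (16, 16)))
        b = self._m(rng.integers(0, 2, (16, 16)))
        assert segmentation_f1(a, b, "tumour") == segmentation_f1(b, a, "tumour")

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_f1(self._m(np.zeros((4, 4))), self._m(np.zeros((5, 5))), "tumour")

    def test_both_empty_is_one(self):
        assert segmentation_f1(self._m(np.zeros((4, 4))), self._m(np.zeros((4, 4))),
                               "tumour") == 1.0


class TestConfidenceSweep:
    def test_gate_separates_fps(self):
        """All FPs below 0.35, all TPs at or above: F1 is 1 from 0.35 up to the
        lowest TP confidence, and the reported optimum is <= 0.35."""
        gt = np.array([[i * 20.0, 0.0] for i in range(8)])
        pred = np.vstack([gt, [[500.0, 0.0], [540.0, 0.0]]])
        conf = np.concatenate([np.linspace(0.4, 1.0, 8), [0.2, 0.3]])
        table, best = confidence_sweep(_pts(pred, conf), _pts(gt),
                                       np.round(np.arange(0.0, 1.0, 0.05), 2), CFG)
        at_035 = table.loc[table["threshold"] == 0.35, "f1"].iloc[0]
        assert at_035 == 1.0
        assert best <= 0.35

    def test_threshold_above_all_confidences(self):
        gt = _pts([[0.0, 0.0]])
        pred = _pts([[0.0, 0.0]], [0.5])
        table, _ = confidence_sweep(pred, gt, [0.9], CFG)
        row = table.iloc[0]
        assert row["precision"] == 0.0 and row["recall"] == 0.0

    def test_zero_threshold_equals_unfiltered(self, rng):
        pred = _pts(rng.uniform(0, 50, (20, 2)), rng.random(20))
        gt = _pts(rng.uniform(0, 50, (15, 2)))
        table, _ = confidence_sweep(pred, gt, [0.0], CFG)
        res = match_points(pred, gt, CFG)
        assert table.iloc[0]["f1"] == pytest.approx(res.f1)

    def test_rejects_out_of_range_thresholds(self):
        with pytest.raises(ValueError):
            confidence_sweep(PointSet.empty(), PointSet.empty(), [1.5], CFG)
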