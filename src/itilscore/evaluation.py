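"""Detection and segmentation evaluation against ground truth.

Point detections are matched one-to-one to ground-truth annotations within a
Euclidean radius (default 4 um, half the ~8 um average TIL diameter); from
the matching follow precision, recall, F1, the average precision over the
confidence-ranked detections, and the confidence-threshold sweep used to pick
an operating point.  Segmentation masks are compared per class with the
pixel-level F1 (Dice) score.

Empty-set conventions (they vary across toolkits, so they are pinned here):
with a nonempty ground truth, an empty prediction set has precision 0,
recall 0, F1 0; with both sets empty all metrics are 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .geometry import LabelRaster
from .points import PointSet

__all__ = [
    "EvalConfig",
    "MatchResult",
    "match_points",
    "average_precision",
    "segmentation_f1",
    "confidence_sweep",
]


@dataclass(frozen=True)
class EvalConfig:
    match_radius_um: float = 4.0
    matching_policy: str = "greedy"  # "greedy" (by confidence) or "optimal"

    def __post_init__(self) -> None:
        if self.match_radius_um <= 0:
            raise ValueError("match radius must be positive")
        if self.matching_policy not in ("greedy", "optimal"):
            raise ValueError(f"unknown matching policy {self.matching_policy!r}")


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple            # (pred_idx, gt_idx, distance_um)
    unmatched_pred: tuple   # false positives
    unmatched_gt: tuple     # false negatives

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0 if self.fp == 0 else 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if self.tp + self.fp + self.fn == 0:
            return 1.0
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _greedy_match(pred: PointSet, gt: PointSet, radius: float):
    """Confidence-descending greedy matching, nearest unmatched ground truth first."""
    order = np.lexsort((pred.xy_um[:, 0], pred.xy_um[:, 1], -pred.confidence))
    tree = cKDTree(gt.xy_um)
    taken = np.zeros(len(gt), dtype=bool)
    pairs = []
    for i in order:
        cand = tree.query_ball_point(pred.xy_um[i], r=radius)
        cand = [j for j in cand if not taken[j]]
        if not cand:
            continue
        d = np.linalg.norm(gt.xy_um[cand] - pred.xy_um[i], axis=1)
        j = cand[int(np.argmin(d))]
        taken[j] = True
        pairs.append((int(i), int(j), float(d.min())))
    return pairs


def _optimal_match(pred: PointSet, gt: PointSet, radius: float):
    """Maximum-cardinality, minimum-distance one-to-one assignment within radius."""
    d = np.linalg.norm(pred.xy_um[:, None, :] - gt.xy_um[None, :, :], axis=2)
    big = radius * 1e6 + 1.0
    cost = np.where(d <= radius, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j), float(d[i, j])) for i, j in zip(rows, cols) if d[i, j] <= radius]


def match_points(pred: PointSet, gt: PointSet, config: EvalConfig | None = None) -> MatchResult:
    """One-to-one matching of predictions to ground truth within the radius."""
    config = config or EvalConfig()
    if len(pred) == 0 or len(gt) == 0:
        return MatchResult((), tuple(range(len(pred))), tuple(range(len(gt))))
    if config.matching_policy == "greedy":
        pairs = _greedy_match(pred, gt, config.match_radius_um)
    else:
        pairs = _optimal_match(pred, gt, config.match_radius_um)
    matched_p = {p for p, _, _ in pairs}
    matched_g = {g for _, g, _ in pairs}
    return MatchResult(tuple(pairs),
                       tuple(i for i in range(len(pred)) if i not in matched_p),
                       tuple(j for j in range(len(gt)) if j not in matched_g))


def average_precision(pred: PointSet, gt: PointSet, config: EvalConfig | None = None) -> float:
    """Area under the precision-recall curve traced by descending confidence.

    All-points integration: AP = sum over confidence ranks of
    (R_k - R_{k-1}) * P_k, with matching re-evaluated at each distinct
    confidence threshold.  Returns 0 for an empty ground truth with
    predictions present, 1 when both sets are empty.
    """
    config = config or EvalConfig()
    if len(gt) == 0:
        return 1.0 if len(pred) == 0 else 0.0
    if len(pred) == 0:
        return 0.0
    thresholds = np.unique(pred.confidence)[::-1]
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        sub = pred.select(pred.confidence >= t)
        res = match_points(sub, gt, config)
        ap += (res.recall - prev_recall) * res.precision
        prev_recall = res.recall
    return float(ap)


def segmentation_f1(pred_mask: LabelRaster, gt_mask: LabelRaster, cls: str) -> float:
    """Pixel-level F1 (Dice) for one class: 2|A n B| / (|A| + |B|).

    Both masks must share extent and resolution.  If the class is empty in
    both masks the score is 1 (perfect vacuous agreement).
    """
    if pred_mask.shape != gt_mask.shape or abs(pred_mask.mpp - gt_mask.mpp) > 1e-9:
        raise ValueError("masks must share extent and mpp")
    a, b = pred_mask.mask(cls), gt_mask.mask(cls)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def confidence_sweep(pred: PointSet, gt: PointSet, thresholds: Sequence[float],
                     config: EvalConfig | None = None) -> tuple[pd.DataFrame, float]:
    """Detection metrics per confidence threshold plus the F1-maximising one.

    Predictions below each threshold are discarded before matching.  Ties in
    F1 resolve to the lowest threshold.
    """
    config = config or EvalConfig()
    thresholds = list(thresholds)
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    rows = []
    for t in sorted(thresholds):
        sub = pred.select(pred.confidence >= t)
        res = match_points(sub, gt, config)
        rows.append({"threshold": t, "n_pred": len(sub), "tp": res.tp, "fp": res.fp,
                     "fn": res.fn, "precision": res.precision, "recall": res.recall,
                     "f1": res.f1})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["f1"].idxmax(), "threshold"])  # idxmax -> first (lowest)
    return table, best
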