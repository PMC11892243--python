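"""Point-detection codec: Gaussian heatmaps <-> confidence-scored points.

TIL detection is framed as heatmap regression: annotated lymphocyte centres
become isotropic 2-D Gaussians (peak 1.0) in a target heatmap; a model's
predicted heatmap is decoded back to points by local-maximum blob detection
with a confidence gate, and duplicates across overlapping tiles are removed
by point-based non-maximum suppression (NMS) in the shared micron frame.

Overlapping Gaussians combine by pixel-wise maximum (not sum) so a peak value
is always a calibrated confidence in [0, 1] — the detection gate (default
0.35) thresholds exactly that value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .geometry import Tile, TilePlan

__all__ = [
    "PointSet",
    "HeatmapSpec",
    "DetectionConfig",
    "encode_points",
    "decode_heatmap",
    "point_nms",
    "merge_tile_detections",
]


@dataclass(frozen=True)
class PointSet:
    """Detections or annotations in micron coordinates.

    ``xy_um`` is an (N, 2) float array of (x, y); ``confidence`` an (N,) array
    in [0, 1]; ``compartment`` an optional (N,) array of string labels
    (``tumour`` / ``stroma`` / ``necrosis`` / ``unassigned``).
    """

    xy_um: np.ndarray
    confidence: np.ndarray = None  # type: ignore[assignment]
    compartment: np.ndarray | None = None

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy_um, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "xy_um", xy)
        conf = self.confidence
        conf = np.ones(len(xy)) if conf is None else np.asarray(conf, dtype=float).reshape(-1)
        if conf.shape[0] != xy.shape[0]:
            raise ValueError("confidence length mismatch")
        if len(conf) and (conf.min() < -1e-9 or conf.max() > 1 + 1e-9):
            raise ValueError("confidence must lie in [0, 1]")
        object.__setattr__(self, "confidence", conf)
        if self.compartment is not None:
            comp = np.asarray(self.compartment, dtype=object).reshape(-1)
            if comp.shape[0] != xy.shape[0]:
                raise ValueError("compartment length mismatch")
            object.__setattr__(self, "compartment", comp)

    def __len__(self) -> int:
        return self.xy_um.shape[0]

    @classmethod
    def empty(cls) -> "PointSet":
        return cls(np.empty((0, 2)), np.empty(0))

    def select(self, idx) -> "PointSet":
        return PointSet(self.xy_um[idx],
                        self.confidence[idx],
                        None if self.compartment is None else self.compartment[idx])

    def with_compartment(self, compartment: np.ndarray) -> "PointSet":
        return PointSet(self.xy_um, self.confidence, np.asarray(compartment, dtype=object))

    def translated(self, dx_um: float, dy_um: float) -> "PointSet":
        return PointSet(self.xy_um + np.array([dx_um, dy_um]), self.confidence, self.compartment)

    @staticmethod
    def concatenate(sets: Sequence["PointSet"]) -> "PointSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return PointSet.empty()
        comp = None
        if all(s.compartment is not None for s in sets):
            comp = np.concatenate([s.compartment for s in sets])
        return PointSet(np.vstack([s.xy_um for s in sets]),
                        np.concatenate([s.confidence for s in sets]), comp)


@dataclass(frozen=True)
class HeatmapSpec:
    """Rendering spec for Gaussian target heatmaps."""

    sigma_um: float = 2.0     # std of the per-point Gaussian; ~TIL nucleus quarter-diameter
    peak_value: float = 1.0
    mpp: float = 0.25         # 40x detection resolution

    def __post_init__(self) -> None:
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be positive")

    @property
    def sigma_px(self) -> float:
        return self.sigma_um / self.mpp


@dataclass(frozen=True)
class DetectionConfig:
    """Decoding and deduplication parameters."""

    confidence_threshold: float = 0.35
    min_separation_um: float = 4.0  # half the ~8 um average TIL diameter
    nms_radius_um: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.min_separation_um <= 0 or self.nms_radius_um <= 0:
            raise ValueError("radii must be positive")


def encode_points(points: PointSet, extent_px: tuple[int, int], spec: HeatmapSpec) -> np.ndarray:
    """Render points as a Gaussian target heatmap.

    Each point contributes an isotropic Gaussian of peak ``spec.peak_value``
    centred on its nearest pixel (pixel centres at ``(i + 0.5) * mpp``);
    overlapping contributions combine by pixel-wise maximum and the result is
    clipped to [0, 1].
    """
    w, h = extent_px
    heat = np.zeros((h, w), dtype=np.float64)
    if len(points) == 0:
        return heat
    sigma = spec.sigma_px
    half = max(1, int(np.ceil(4.0 * sigma)))
    cols = np.rint(points.xy_um[:, 0] / spec.mpp - 0.5).astype(int)
    rows = np.rint(points.xy_um[:, 1] / spec.mpp - 0.5).astype(int)
    for r, c in zip(rows, cols):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1) - r
        xx = np.arange(c0, c1) - c
        g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sigma * sigma))
        np.maximum(heat[r0:r1, c0:c1], spec.peak_value * g, out=heat[r0:r1, c0:c1])
    return np.clip(heat, 0.0, 1.0)


def decode_heatmap(heatmap: np.ndarray, config: DetectionConfig, mpp: float) -> PointSet:
    """Blob-decode a heatmap into confidence-scored points.

    Local maxima with value >= ``confidence_threshold`` become points (pixel
    centres mapped to microns, confidence = peak value); survivors closer than
    ``min_separation_um`` are reduced by greedy NMS so the returned points are
    pairwise separated.  Points come back sorted by confidence descending.
    """
    heatmap = np.asarray(heatmap, dtype=float)
    # A zero-confidence "detection" is meaningless, so the gate is effectively
    # max(threshold, tiny positive) — an all-zero heatmap decodes to nothing.
    floor = max(config.confidence_threshold, 1e-9)
    if heatmap.size == 0 or float(heatmap.max(initial=0.0)) < floor:
        return PointSet.empty()
    min_dist_px = max(1, int(np.floor(config.min_separation_um / mpp)))
    # skimage thresholds strictly; nudge down so peaks exactly at the gate
    # survive (the gate is inclusive).  exclude_border=False keeps
    # seam-adjacent peaks (cross-tile duplicates are NMS'd later).
    peaks = peak_local_max(heatmap, min_distance=min_dist_px,
                           threshold_abs=floor - 1e-12,
                           exclude_border=False)
    if peaks.size == 0:
        return PointSet.empty()
    conf = heatmap[peaks[:, 0], peaks[:, 1]]
    ok = conf >= floor - 1e-9
    peaks, conf = peaks[ok], conf[ok]
    if peaks.size == 0:
        return PointSet.empty()
    xy = np.column_stack([(peaks[:, 1] + 0.5) * mpp, (peaks[:, 0] + 0.5) * mpp])
    # peak_local_max separates in Chebyshev distance; enforce Euclidean separation.
    return point_nms(PointSet(xy, np.clip(conf, 0, 1)), config.min_separation_um)


def point_nms(points: PointSet, radius_um: float) -> PointSet:
    """Greedy confidence-descending non-maximum suppression.

    Points are visited by decreasing confidence (ties broken by (y, x)
    lexicographic order for reproducibility); a point within ``radius_um``
    (inclusive) of an already-kept point is suppressed.  The result is sorted
    by confidence descending and is idempotent.
    """
    n = len(points)
    if n == 0:
        return points
    if not np.all(np.isfinite(points.confidence)):
        raise ValueError("confidences must be finite")
    order = np.lexsort((points.xy_um[:, 0], points.xy_um[:, 1], -points.confidence))
    xy = points.xy_um[order]
    tree = cKDTree(xy)
    neighbours = tree.query_ball_point(xy, r=radius_um)
    keep_mask = np.zeros(n, dtype=bool)
    suppressed = np.zeros(n, dtype=bool)
    for i in range(n):
        if suppressed[i]:
            continue
        keep_mask[i] = True
        for j in neighbours[i]:
            if j > i:
                suppressed[j] = True
    kept = order[keep_mask]
    return points.select(kept)


def merge_tile_detections(per_tile: Sequence[tuple[Tile, PointSet]],
                          plan: TilePlan,
                          config: DetectionConfig,
                          origin_um: tuple[float, float] = (0.0, 0.0)) -> PointSet:
    """Merge tile-local detections (pixel coordinates) into one global point set.

    Tile-local pixel coordinates are shifted into the shared micron frame via
    the tile's position in ``plan``, then deduplicated with
    :func:`point_nms` at ``config.nms_radius_um`` so a TIL visible in two
    overlapping tiles is counted once.
    """
    plan_tiles = {t.index: t for t in plan.tiles}
    ox, oy = origin_um
    globals_: list[PointSet] = []
    for tile, pts in per_tile:
        ref = plan_tiles.get(tile.index)
        if ref is None or (ref.x0, ref.y0, ref.x1, ref.y1) != (tile.x0, tile.y0, tile.x1, tile.y1):
            raise ValueError(f"tile {tile.index} is not part of the plan")
        if len(pts) == 0:
            continue
        xy_um = (pts.xy_um + np.array([tile.x0, tile.y0])) * plan.mpp + np.array([ox, oy])
        globals_.append(PointSet(xy_um, pts.confidence, pts.compartment))
    merged = PointSet.concatenate(globals_)
    return point_nms(merged, config.nms_radius_um)
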