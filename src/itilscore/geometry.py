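"""Slide geometry: micron/pixel mapping, tile planning, raster reconstruction.

The whole pipeline lives in one shared micron coordinate frame.  A raster at
``mpp`` microns per pixel with origin ``origin_um`` places pixel ``(row, col)``
over the half-open micron rectangle

    [origin_x + col * mpp, origin_x + (col + 1) * mpp)
  x [origin_y + row * mpp, origin_y + (row + 1) * mpp)

i.e. a pixel's micron position is its top-left corner.  Pixel indices are
0-based with the origin at the top-left of the slide.  The three inference
stages run at 4.0 MPP (broad cancer segmentation, ~2.5x), 0.5 MPP (tumour /
stroma / necrosis, ~20x) and 0.25 MPP (TIL detection, ~40x), all aligned in
this single frame so masks and points at different resolutions can be looked
up against each other without registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ResolutionSpec",
    "Tile",
    "TilePlan",
    "LabelRaster",
    "plan_tiles",
    "reconstruct_raster",
    "class_area_mm2",
    "downsample_rgb",
    "resample_rgb_to_mpp",
    "upsample_labels",
]

#: Stage resolutions used by the pipeline (microns per pixel).
BROAD_MPP = 4.0
TSN_MPP = 0.5
TIL_MPP = 0.25


@dataclass(frozen=True)
class ResolutionSpec:
    """A working resolution, e.g. ``ResolutionSpec(0.25, "40x")``."""

    mpp: float
    magnification_label: str = ""

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")


@dataclass(frozen=True)
class Tile:
    """One tile of a :class:`TilePlan`; pixel bounds are half-open."""

    index: int
    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def micron_bounds(self, mpp: float, origin_um: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float, float, float]:
        """(x0_um, y0_um, x1_um, y1_um) of the tile in the shared frame."""
        ox, oy = origin_um
        return (ox + self.x0 * mpp, oy + self.y0 * mpp,
                ox + self.x1 * mpp, oy + self.y1 * mpp)


@dataclass(frozen=True)
class TilePlan:
    extent_px: tuple[int, int]  # (width, height)
    tile_size_px: int
    overlap_px: int
    mpp: float
    tiles: tuple[Tile, ...] = field(default_factory=tuple)

    @property
    def stride(self) -> int:
        return self.tile_size_px - self.overlap_px

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


def plan_tiles(extent_px: tuple[int, int], tile_size_px: int = 512,
               overlap_px: int = 0, mpp: float = 1.0) -> TilePlan:
    """Plan a full-coverage tiling of a ``(width, height)`` pixel extent.

    Tiles are laid out row-major on a regular grid with stride
    ``tile_size_px - overlap_px``; edge tiles are clipped to the extent (never
    padded), so the rightmost/bottom tiles may be smaller than
    ``tile_size_px``.  With ``overlap_px == 0`` the tiles partition the extent.
    """
    w, h = int(extent_px[0]), int(extent_px[1])
    if w <= 0 or h <= 0:
        raise ValueError(f"extent must be positive, got {(w, h)}")
    if tile_size_px <= 0:
        raise ValueError(f"tile size must be positive, got {tile_size_px}")
    if not 0 <= overlap_px < tile_size_px:
        raise ValueError(f"overlap must satisfy 0 <= overlap < tile size, got {overlap_px}")
    if mpp <= 0:
        raise ValueError(f"mpp must be positive, got {mpp}")

    stride = tile_size_px - overlap_px
    xs = list(range(0, w, stride))
    ys = list(range(0, h, stride))
    # Drop grid positions that only re-cover already-covered pixels (can occur
    # with overlap when the previous tile already reaches the extent edge).
    xs = [x for i, x in enumerate(xs) if i == 0 or xs[i - 1] + tile_size_px < w]
    ys = [y for i, y in enumerate(ys) if i == 0 or ys[i - 1] + tile_size_px < h]

    tiles = []
    idx = 0
    for y0 in ys:
        for x0 in xs:
            tiles.append(Tile(idx, x0, y0, min(x0 + tile_size_px, w), min(y0 + tile_size_px, h)))
            idx += 1
    return TilePlan((w, h), tile_size_px, overlap_px, mpp, tuple(tiles))


@dataclass
class LabelRaster:
    """Categorical per-pixel grid with physical calibration.

    Parameters
    ----------
    grid : (H, W) integer array of class codes.
    mpp : microns per pixel.
    class_map : mapping from class name to integer code.
    origin_um : micron position of the top-left corner of pixel (0, 0).
    """

    grid: np.ndarray
    mpp: float
    class_map: Mapping[str, int]
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    # -- basic queries ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # (H, W)

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width_um, height_um) of the raster."""
        h, w = self.grid.shape
        return (w * self.mpp, h * self.mpp)

    def code(self, cls: str) -> int:
        try:
            return self.class_map[cls]
        except KeyError:
            raise ValueError(f"unknown class {cls!r}; known: {sorted(self.class_map)}") from None

    def mask(self, cls: str) -> np.ndarray:
        return self.grid == self.code(cls)

    def area_mm2(self, cls: str) -> float:
        """Area of class ``cls`` in mm**2 (pixel count x (mpp/1000)**2)."""
        return float(np.count_nonzero(self.mask(cls))) * (self.mpp / 1000.0) ** 2

    # -- micron-frame lookup ------------------------------------------------

    def pixel_index(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """Map micron coordinates to (row, col) indices (floor; may be out of range)."""
        ox, oy = self.origin_um
        col = np.floor((np.asarray(x_um, dtype=float) - ox) / self.mpp).astype(np.int64)
        row = np.floor((np.asarray(y_um, dtype=float) - oy) / self.mpp).astype(np.int64)
        return row, col

    def lookup(self, x_um, y_um, outside: int = -1) -> np.ndarray:
        """Class code at each micron coordinate; ``outside`` for out-of-extent points."""
        row, col = self.pixel_index(x_um, y_um)
        h, w = self.grid.shape
        inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.full(np.shape(row), outside, dtype=np.int64)
        out[inside] = self.grid[row[inside], col[inside]]
        return out

    def bbox_um(self, cls: str) -> tuple[float, float, float, float] | None:
        """Tight micron bounding box (x0, y0, x1, y1) of class pixels, or None."""
        m = self.mask(cls)
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        if rows.size == 0:
            return None
        ox, oy = self.origin_um
        return (ox + cols[0] * self.mpp, oy + rows[0] * self.mpp,
                ox + (cols[-1] + 1) * self.mpp, oy + (rows[-1] + 1) * self.mpp)


def class_area_mm2(raster: LabelRaster, cls: str) -> float:
    """Area of class ``cls`` in mm**2 of ``raster``."""
    return raster.area_mm2(cls)


def reconstruct_raster(per_tile_predictions: Sequence[tuple[Tile, np.ndarray]],
                       plan: TilePlan,
                       class_map: Mapping[str, int],
                       origin_um: tuple[float, float] = (0.0, 0.0)) -> LabelRaster:
    """Stitch per-tile class grids back into a slide-level :class:`LabelRaster`.

    Every tile of ``plan`` must appear exactly once with a grid of matching
    shape.  Where tiles overlap, the prediction written later in row-major
    tile order wins (last-writer-wins seam policy).
    """
    w, h = plan.extent_px
    provided = {t.index: (t, np.asarray(g)) for t, g in per_tile_predictions}
    missing = [t.index for t in plan.tiles if t.index not in provided]
    if missing:
        raise ValueError(f"missing predictions for tiles {missing[:10]}")
    out = np.zeros((h, w), dtype=np.asarray(per_tile_predictions[0][1]).dtype)
    for tile in plan.tiles:  # row-major order -> deterministic seam policy
        t, grid = provided[tile.index]
        if grid.shape != (t.height, t.width):
            raise ValueError(
                f"tile {t.index}: prediction shape {grid.shape} != tile shape {(t.height, t.width)}")
        out[t.y0:t.y1, t.x0:t.x1] = grid
    return LabelRaster(out, plan.mpp, class_map, origin_um)


# -- resampling -------------------------------------------------------------


def downsample_rgb(rgb: np.ndarray, factor: int) -> np.ndarray:
    """Area-weighted (block-mean) downsampling of an RGB image by an integer factor.

    Trailing rows/columns that do not fill a complete block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return rgb
    h, w = rgb.shape[:2]
    hh, ww = h // factor, w // factor
    # slice-accumulate in integers: much faster and leaner than a float mean
    acc_dtype = np.uint16 if factor * factor * 255 <= np.iinfo(np.uint16).max else np.uint32
    acc = np.zeros((hh, ww) + rgb.shape[2:], dtype=acc_dtype)
    for i in range(factor):
        for j in range(factor):
            acc += rgb[i: hh * factor: factor, j: ww * factor: factor]
    n = factor * factor
    return ((acc + n // 2) // n).astype(np.uint8)


def resample_rgb_to_mpp(rgb: np.ndarray, src_mpp: float, dst_mpp: float) -> np.ndarray:
    """Resample an RGB raster from ``src_mpp`` to ``dst_mpp``.

    Integer downsampling ratios use fast block averaging; anything else falls
    back to anti-aliased interpolation.
    """
    if abs(src_mpp - dst_mpp) < 1e-9:
        return rgb
    ratio = dst_mpp / src_mpp
    if ratio > 1 and abs(ratio - round(ratio)) < 1e-6:
        return downsample_rgb(rgb, int(round(ratio)))
    h, w = rgb.shape[:2]
    out_shape = (max(1, int(round(h / ratio))), max(1, int(round(w / ratio))))
    out = _sk_resize(rgb.astype(np.float32), out_shape + rgb.shape[2:],
                     order=1, anti_aliasing=ratio > 1, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def upsample_labels(raster: LabelRaster, dst_mpp: float) -> LabelRaster:
    """Nearest-neighbour resampling of a label raster to a finer integer-ratio mpp."""
    ratio = raster.mpp / dst_mpp
    f = int(round(ratio))
    if abs(ratio - f) > 1e-6 or f < 1:
        raise ValueError(f"mpp ratio {ratio} is not a positive integer")
    if f == 1:
        return raster
    grid = np.repeat(np.repeat(raster.grid, f, axis=0), f, axis=1)
    return LabelRaster(grid, dst_mpp, dict(raster.class_map), raster.origin_um)
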