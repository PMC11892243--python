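"""Model-stage contracts and deterministic toy backends.

The pipeline has three inference stages, each a pluggable backend operating on
512 x 512 px RGB tiles at a fixed resolution:

=======  ========  =====================================  =================
stage    mpp       output per tile                        decoded as
=======  ========  =====================================  =================
broad    4.0       class probabilities (other, cancer)    argmax label mask
tsn      0.5       class probabilities (t / s / n)        argmax label mask
til      0.25      TIL likelihood heatmap in [0, 1]       blob points
=======  ========  =====================================  =================

In production these would be trained segmentation / heatmap-regression
networks; adapters for such models plug in behind the same ``predict``
contract.  The toy backends shipped here are deterministic pixel rules keyed
to the synthetic renderer's palette, so the complete pipeline runs and can be
verified against exact ground truth without any trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy.signal import fftconvolve

from .geometry import (BROAD_MPP, TIL_MPP, TSN_MPP, LabelRaster, TilePlan,
                       plan_tiles, reconstruct_raster, resample_rgb_to_mpp)
from .points import DetectionConfig, PointSet, decode_heatmap, merge_tile_detections
from .synthetic import BROAD_CLASSES, PALETTE, TIL_DISK_RADIUS_UM, TSN_CLASSES

__all__ = [
    "BackendSpec",
    "Backend",
    "PipelineError",
    "ToyBroadBackend",
    "ToyTSNBackend",
    "ToyTILBackend",
    "RandomBackend",
    "BACKEND_REGISTRY",
    "make_backend",
    "run_broad_segmentation",
    "run_tsn_segmentation",
    "run_til_detection",
]

STAGE_MPP = {"broad": BROAD_MPP, "tsn": TSN_MPP, "til": TIL_MPP}


@dataclass(frozen=True)
class BackendSpec:
    """Contract metadata for one model stage."""

    stage: str                 # "broad" | "tsn" | "til"
    input_mpp: float
    tile_size_px: int = 512
    output_kind: str = "probabilities"  # or "heatmap"

    def __post_init__(self) -> None:
        if self.stage not in STAGE_MPP:
            raise ValueError(f"unknown stage {self.stage!r}")
        if abs(self.input_mpp - STAGE_MPP[self.stage]) > 1e-9:
            raise ValueError(
                f"stage {self.stage!r} runs at {STAGE_MPP[self.stage]} MPP, got {self.input_mpp}")


class Backend(Protocol):
    spec: BackendSpec

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        """(H, W, C) class probabilities or (H, W) heatmap for an RGB tile."""
        ...


class PipelineError(RuntimeError):
    """A backend failed on a tile; the message names the tile index."""


_LUT_CACHE: dict[bytes, np.ndarray] = {}


def _palette_lut(colours: np.ndarray) -> np.ndarray:
    """(64, 64, 64) nearest-palette-index table over 4-level-quantised RGB.

    Palette colours are tens of intensity levels apart while the quantisation
    error is at most 2 levels per channel, so the quantised lookup agrees with
    the exact nearest-colour rule everywhere except exactly equidistant
    boundary colours (which no renderer output produces).
    """
    key = colours.tobytes()
    lut = _LUT_CACHE.get(key)
    if lut is None:
        centres = np.arange(64) * 4.0 + 1.5
        r, g, b = np.meshgrid(centres, centres, centres, indexing="ij")
        bins = np.stack([r, g, b], axis=-1).reshape(-1, 3)
        d2 = ((bins[:, None, :] - colours[None, :, :]) ** 2).sum(axis=2)
        lut = d2.argmin(axis=1).astype(np.uint8).reshape(64, 64, 64)
        _LUT_CACHE[key] = lut
    return lut


def _nearest_palette(tile_rgb: np.ndarray, colours: np.ndarray) -> np.ndarray:
    """Index of the nearest palette colour per pixel (L2 in RGB, quantised LUT)."""
    lut = _palette_lut(np.asarray(colours, dtype=float))
    return lut[tile_rgb[..., 0] >> 2, tile_rgb[..., 1] >> 2, tile_rgb[..., 2] >> 2]


class ToyBroadBackend:
    """Colour-rule broad cancer segmentation on the synthetic palette.

    A pixel is cancerous when its nearest palette colour is any of the
    within-cancer classes (tumour/stroma/necrosis or a TIL colour).
    """

    spec = BackendSpec("broad", BROAD_MPP, output_kind="probabilities")
    _names = ["background", "tumour", "stroma", "necrosis", "til_tumour", "til_stroma"]
    _cancerous = np.array([False, True, True, True, True, True])

    def __init__(self) -> None:
        self._colours = np.array([PALETTE[n] for n in self._names])

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        nearest = _nearest_palette(tile_rgb, self._colours)
        cancer = self._cancerous[nearest]
        probs = np.zeros(tile_rgb.shape[:2] + (2,), dtype=np.float32)
        probs[..., BROAD_CLASSES["cancer"]] = cancer
        probs[..., BROAD_CLASSES["other"]] = ~cancer
        return probs


class ToyTSNBackend:
    """Colour-rule tumour/stroma/necrosis segmentation on the synthetic palette.

    TIL-coloured pixels map to their host compartment (a trained model labels
    lymphocyte pixels by the tissue they sit in).  Output channels follow
    ``TSN_CLASSES`` order (other, tumour, stroma, necrosis).
    """

    spec = BackendSpec("tsn", TSN_MPP, output_kind="probabilities")
    _names = ["background", "tumour", "stroma", "necrosis", "til_tumour", "til_stroma"]
    _to_class = np.array([TSN_CLASSES["other"], TSN_CLASSES["tumour"], TSN_CLASSES["stroma"],
                          TSN_CLASSES["necrosis"], TSN_CLASSES["tumour"], TSN_CLASSES["stroma"]])

    def __init__(self) -> None:
        self._colours = np.array([PALETTE[n] for n in self._names])

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        nearest = _nearest_palette(tile_rgb, self._colours)
        cls = self._to_class[nearest]
        probs = np.zeros(tile_rgb.shape[:2] + (len(TSN_CLASSES),), dtype=np.float32)
        h, w = cls.shape
        probs.reshape(-1, len(TSN_CLASSES))[np.arange(h * w), cls.ravel()] = 1.0
        return probs


class ToyTILBackend:
    """Disk-template TIL detector emitting a pseudo-heatmap.

    Pixels matching a TIL palette colour (within ``colour_tol`` per channel)
    form a binary mask that is correlated with a disk kernel of the rendered
    lymphocyte radius, normalised so an isolated full disk peaks at exactly
    1.0 at its centre.  Matching on the TIL-colour mask rather than raw
    intensity keeps the response zero along compartment boundaries.
    """

    spec = BackendSpec("til", TIL_MPP, output_kind="heatmap")

    def __init__(self, disk_radius_um: float = TIL_DISK_RADIUS_UM, colour_tol: int = 40) -> None:
        self.colour_tol = colour_tol
        r_px = disk_radius_um / TIL_MPP
        rr = int(np.ceil(r_px))
        dy, dx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        self._kernel = ((dx * dx + dy * dy) <= r_px * r_px).astype(np.float32)
        self._kernel /= self._kernel.sum()
        self._til_colours = np.array([PALETTE["til_tumour"], PALETTE["til_stroma"]], dtype=np.int16)

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        # Cheap pre-screen: TIL colours are far darker in red than any tissue
        # colour, so only dark-red pixels need the exact colour test.
        red_max = int(max(c[0] for c in self._til_colours)) + self.colour_tol
        cand = tile_rgb[..., 0] <= red_max
        if not cand.any():
            return np.zeros(tile_rgb.shape[:2], dtype=np.float32)
        vals = tile_rgb[cand].astype(np.int16)
        hit = np.zeros(len(vals), dtype=bool)
        for colour in self._til_colours:
            hit |= np.abs(vals - colour).max(axis=1) <= self.colour_tol
        mask = np.zeros(tile_rgb.shape[:2], dtype=bool)
        mask[cand] = hit
        if not mask.any():
            return np.zeros(tile_rgb.shape[:2], dtype=np.float32)
        heat = fftconvolve(mask.astype(np.float32), self._kernel, mode="same")
        return np.clip(heat, 0.0, 1.0).astype(np.float32)


class RandomBackend:
    """Seeded random-output backend satisfying the stage contract.

    Used in contract tests: any backend with valid outputs must yield a valid
    (if meaningless) slide score downstream.
    """

    def __init__(self, stage: str, seed: int = 0) -> None:
        kind = "heatmap" if stage == "til" else "probabilities"
        self.spec = BackendSpec(stage, STAGE_MPP[stage], output_kind=kind)
        self._seed = seed

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        h, w = tile_rgb.shape[:2]
        # hash the tile content so outputs are deterministic per tile
        digest = int(np.uint64(tile_rgb[::16, ::16].sum())) ^ self._seed
        rng = np.random.default_rng(digest % (2 ** 31))
        if self.spec.output_kind == "heatmap":
            return rng.random((h, w), dtype=np.float32)
        c = 2 if self.spec.stage == "broad" else len(TSN_CLASSES)
        p = rng.random((h, w, c)).astype(np.float32)
        return p / p.sum(axis=2, keepdims=True)


BACKEND_REGISTRY: dict[str, Callable[[], Backend]] = {
    "toy-broad": ToyBroadBackend,
    "toy-tsn": ToyTSNBackend,
    "toy-til": ToyTILBackend,
}


def make_backend(name: str) -> Backend:
    try:
        return BACKEND_REGISTRY[name]()
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; registered: {sorted(BACKEND_REGISTRY)}") from None


# -- stage runners -----------------------------------------------------------


def _run_tiled(rgb: np.ndarray, backend: Backend, plan: TilePlan, stage: str):
    out = []
    for tile in plan:
        try:
            pred = backend.predict(rgb[tile.y0:tile.y1, tile.x0:tile.x1])
        except Exception as exc:  # noqa: BLE001 - re-raise with tile context
            raise PipelineError(f"{stage} backend failed on tile {tile.index}: {exc}") from exc
        out.append((tile, pred))
    return out


def run_broad_segmentation(slide_rgb: np.ndarray, slide_mpp: float, backend: Backend,
                           tile_size_px: int = 512, overlap_px: int = 0,
                           origin_um: tuple[float, float] = (0.0, 0.0)) -> LabelRaster:
    """Stage 1: broad cancer-vs-other segmentation of the whole slide at 4 MPP."""
    rgb = resample_rgb_to_mpp(slide_rgb, slide_mpp, BROAD_MPP)
    h, w = rgb.shape[:2]
    plan = plan_tiles((w, h), tile_size_px, overlap_px, BROAD_MPP)
    preds = [(t, p.argmax(axis=2).astype(np.uint8))
             for t, p in _run_tiled(rgb, backend, plan, "broad")]
    return reconstruct_raster(preds, plan, dict(BROAD_CLASSES), origin_um)


def run_tsn_segmentation(slide_rgb: np.ndarray, slide_mpp: float, broad_mask: LabelRaster,
                         backend: Backend, tile_size_px: int = 512, overlap_px: int = 0,
                         origin_um: tuple[float, float] = (0.0, 0.0)) -> LabelRaster:
    """Stage 2: tumour/stroma/necrosis segmentation at 0.5 MPP.

    Applied only within broadly cancerous tissue: pixels outside the broad
    cancer mask are labelled ``other`` regardless of the backend's output.
    """
    if abs(broad_mask.mpp - BROAD_MPP) > 1e-9:
        raise ValueError(f"broad mask must be at {BROAD_MPP} MPP, got {broad_mask.mpp}")
    if tuple(broad_mask.origin_um) != tuple(origin_um):
        raise ValueError("broad mask and slide are in different micron frames")
    rgb = resample_rgb_to_mpp(slide_rgb, slide_mpp, TSN_MPP)
    h, w = rgb.shape[:2]
    plan = plan_tiles((w, h), tile_size_px, overlap_px, TSN_MPP)
    preds = [(t, p.argmax(axis=2).astype(np.uint8))
             for t, p in _run_tiled(rgb, backend, plan, "tsn")]
    tsn = reconstruct_raster(preds, plan, dict(TSN_CLASSES), origin_um)
    # nearest-neighbour lookup of the 4 MPP broad mask from the 0.5 MPP grid
    factor = int(round(BROAD_MPP / TSN_MPP))
    rows = np.minimum(np.arange(h) // factor, broad_mask.shape[0] - 1)
    cols = np.minimum(np.arange(w) // factor, broad_mask.shape[1] - 1)
    cancer = broad_mask.mask("cancer")[rows][:, cols]
    tsn.grid[~cancer] = TSN_CLASSES["other"]
    return tsn


def run_til_detection(slide_rgb: np.ndarray, slide_mpp: float, broad_mask: LabelRaster,
                      backend: Backend, config: DetectionConfig | None = None,
                      tile_size_px: int = 512, overlap_px: int = 64,
                      origin_um: tuple[float, float] = (0.0, 0.0)) -> PointSet:
    """Stage 3: TIL point detection at 0.25 MPP within cancerous tissue.

    Tiles overlap by default so a lymphocyte on a seam is fully visible in at
    least one tile; the cross-tile NMS in :func:`merge_tile_detections`
    removes the duplicates.  Detections outside the broad cancer mask are
    discarded after merging.
    """
    config = config or DetectionConfig()
    if tuple(broad_mask.origin_um) != tuple(origin_um):
        raise ValueError("broad mask and slide are in different micron frames")
    rgb = resample_rgb_to_mpp(slide_rgb, slide_mpp, TIL_MPP)
    h, w = rgb.shape[:2]
    plan = plan_tiles((w, h), tile_size_px, overlap_px, TIL_MPP)
    per_tile = []
    for tile in plan:
        try:
            heat = backend.predict(rgb[tile.y0:tile.y1, tile.x0:tile.x1])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"til backend failed on tile {tile.index}: {exc}") from exc
        local = decode_heatmap(heat, config, TIL_MPP)
        # decode returns tile-local microns; merge expects tile-local pixels
        per_tile.append((tile, PointSet(local.xy_um / TIL_MPP, local.confidence)))
    merged = merge_tile_detections(per_tile, plan, config, origin_um)
    if len(merged) == 0:
        return merged
    labels = broad_mask.lookup(merged.xy_um[:, 0], merged.xy_um[:, 1])
    return merged.select(labels == BROAD_CLASSES["cancer"])
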