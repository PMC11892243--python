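"""End-to-end slide analysis: RGB slide in, scored and flagged slide out.

Chains the three backend stages (broad cancer segmentation at 4 MPP, TSN
segmentation at 0.5 MPP, TIL detection at 0.25 MPP), assigns detections to
compartments, scores the HPF-equivalent field grid and evaluates the
reliability flags.  Optional Macenko stain normalisation can be applied
per-tile before inference, as would be done with trained backends on real
scanner data; failures are counted and surface in the flag report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import (Backend, run_broad_segmentation, run_til_detection,
                       run_tsn_segmentation)
from .geometry import BROAD_MPP, LabelRaster, resample_rgb_to_mpp
from .points import DetectionConfig, PointSet
from .scoring import (FlagCriteria, ScoringConfig, SlideScore, assign_compartment,
                      flag_slide, score_slide)
from .stain import StainEstimationError, macenko_normalize

__all__ = ["SlideAnalysis", "analyse_slide"]

WHITE_LUMINANCE = 238  # pixels brighter than this (all channels) count as background


@dataclass
class SlideAnalysis:
    """Everything one slide run produces."""

    slide_score: SlideScore
    broad_mask: LabelRaster
    tsn_mask: LabelRaster
    detections: PointSet            # compartment-assigned, within cancer
    metrics: dict = field(default_factory=dict)


class _StainNormalisingBackend:
    """Wrap a backend so each tile is stain-normalised first; count failures."""

    def __init__(self, inner: Backend) -> None:
        self.inner = inner
        self.spec = inner.spec
        self.failures = 0

    def predict(self, tile_rgb: np.ndarray) -> np.ndarray:
        try:
            tile_rgb = macenko_normalize(tile_rgb)
        except StainEstimationError:
            self.failures += 1  # background-only tile: run on the raw pixels
        return self.inner.predict(tile_rgb)


def analyse_slide(slide_rgb: np.ndarray, slide_mpp: float,
                  broad_backend: Backend, tsn_backend: Backend, til_backend: Backend,
                  detection_config: DetectionConfig | None = None,
                  scoring_config: ScoringConfig | None = None,
                  flag_criteria: FlagCriteria | None = None,
                  slide_id: str = "slide",
                  normalize_stain: bool = False) -> SlideAnalysis:
    """Run the full iTIL scoring pipeline on one RGB slide raster.

    ``slide_rgb`` is an (H, W, 3) uint8 raster at ``slide_mpp`` microns per
    pixel (typically the 40x / 0.25 MPP level); each stage resamples it to its
    own working resolution.  Returns the slide score (with flag report), the
    intermediate masks and the compartment-assigned detections.
    """
    detection_config = detection_config or DetectionConfig()
    scoring_config = scoring_config or ScoringConfig()
    flag_criteria = flag_criteria or FlagCriteria()

    stain_failures = 0
    if normalize_stain:
        broad_backend = _StainNormalisingBackend(broad_backend)
        tsn_backend = _StainNormalisingBackend(tsn_backend)
        til_backend = _StainNormalisingBackend(til_backend)

    broad = run_broad_segmentation(slide_rgb, slide_mpp, broad_backend)
    tsn = run_tsn_segmentation(slide_rgb, slide_mpp, broad, tsn_backend)
    detections = run_til_detection(slide_rgb, slide_mpp, broad, til_backend,
                                   detection_config)
    detections = assign_compartment(detections, tsn)
    slide_score = score_slide(slide_id, tsn, detections, scoring_config)

    if normalize_stain:
        stain_failures = sum(b.failures for b in (broad_backend, tsn_backend, til_backend))

    rgb4 = resample_rgb_to_mpp(slide_rgb, slide_mpp, BROAD_MPP)
    tissue_px = int(np.count_nonzero((rgb4 < WHITE_LUMINANCE).any(axis=2)))
    cancer_px = int(np.count_nonzero(broad.mask("cancer")))
    metrics = {
        "tumour_area_mm2": tsn.area_mm2("tumour"),
        "eligible_field_count": slide_score.eligible_count,
        "cancer_fraction_of_tissue": cancer_px / tissue_px if tissue_px else 0.0,
        "stain_failures": stain_failures,
    }
    slide_score.flag_report = flag_slide(metrics, flag_criteria)
    return SlideAnalysis(slide_score, broad, tsn, detections, metrics)
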