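"""Deterministic synthetic fixtures: tissue layouts, planted TILs, cohorts.

Everything the scoring pipeline consumes can be generated here with known
ground truth: broad cancer masks (4 MPP), tumour/stroma/necrosis masks
(0.5 MPP), RGB slides rendered in a fixed "toy" palette (0.25 MPP), TIL point
processes with planted per-compartment densities, model-like heatmaps with
optional decoy blobs and noise, and survival cohorts with a planted TIL
effect at a known score cut-off.

The renderer is not photorealistic: each tissue class is a flat colour with
small seeded jitter, and lymphocytes are dark disks in a compartment-specific
colour.  That is deliberate — the deterministic colour-rule backends in
:mod:`itilscore.backends` can then act as near-perfect stand-ins for trained
networks, so every downstream code path (tiling, decoding, NMS, compartment
lookup, field scoring, survival) is exercised against exact ground truth.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .geometry import BROAD_MPP, TIL_MPP, TSN_MPP, LabelRaster, upsample_labels
from .points import HeatmapSpec, PointSet, encode_points

__all__ = [
    "PALETTE",
    "BROAD_CLASSES",
    "TSN_CLASSES",
    "LayoutSpec",
    "PlantSpec",
    "CohortSpec",
    "Layout",
    "generate_layout",
    "render_slide_rgb",
    "plant_tils",
    "render_heatmap",
    "generate_cohort",
]

# Toy renderer palette.  TILs get their own colour per host compartment so a
# colour-rule backend can (a) detect them and (b) map the pixel back to the
# compartment the lymphocyte sits in, like a trained TSN model would.
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (245, 244, 240),
    "tumour": (190, 100, 140),
    "stroma": (240, 180, 200),
    "necrosis": (150, 130, 90),
    "til_tumour": (90, 45, 130),
    "til_stroma": (60, 70, 150),
}

BROAD_CLASSES = {"other": 0, "cancer": 1}
TSN_CLASSES = {"other": 0, "tumour": 1, "stroma": 2, "necrosis": 3}

TIL_DISK_RADIUS_UM = 3.0  # rendered lymphocyte disk radius


@dataclass(frozen=True)
class LayoutSpec:
    """Synthetic tissue layout: smooth random cancer blobs partitioned into TSN.

    ``tsn_fractions`` are the requested (tumour, stroma, necrosis) area
    fractions *within* cancerous tissue; realised fractions track them closely
    because the partition thresholds are quantiles of the underlying smooth
    noise field.
    """

    extent_um: tuple[float, float] = (2048.0, 2048.0)
    cancer_fraction: float = 0.5
    tsn_fractions: tuple[float, float, float] = (0.6, 0.35, 0.05)
    blob_scale_um: float = 250.0   # correlation length of the cancer geometry
    tsn_scale_um: float = 120.0    # correlation length of the TSN partition
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise ValueError("cancer_fraction must lie in [0, 1]")
        if abs(sum(self.tsn_fractions) - 1.0) > 1e-9:
            raise ValueError("tsn_fractions must sum to 1")


@dataclass(frozen=True)
class PlantSpec:
    """Planted TIL point process: per-compartment homogeneous Poisson with a
    hard-core (Matern-II style) minimum separation."""

    lambda_tumour: float = 17.0   # iTILs per mm^2 tumour
    lambda_stroma: float = 0.0    # TILs per mm^2 stroma
    min_separation_um: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_tumour < 0 or self.lambda_stroma < 0:
            raise ValueError("densities must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic survival cohort with a planted TIL effect.

    Per-patient iTIL scores are log-normal (median ``score_median``); patients
    whose score falls below ``true_cutoff`` carry ``hazard_ratio`` times the
    baseline exponential hazard.  Censoring is independent exponential; the
    5-year administrative truncation is applied downstream by
    ``censor_at_5_years``, not here.
    """

    n_patients: int = 400
    true_cutoff: float = 17.0
    hazard_ratio: float = 2.0          # TIL-Low vs TIL-High
    baseline_hazard: float = 5.0e-4    # events/day for TIL-High (~60% by 5 y)
    censoring_rate: float = 1.0e-4     # independent censoring events/day
    score_median: float = 17.0
    score_sigma: float = 0.6           # sigma of log score
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class Layout:
    broad: LabelRaster   # {other, cancer} at 4 MPP
    tsn: LabelRaster     # {other, tumour, stroma, necrosis} at 0.5 MPP
    spec: LayoutSpec


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return gaussian_filter(noise, sigma=max(sigma_px, 1.0), mode="reflect")


def generate_layout(spec: LayoutSpec) -> Layout:
    """Generate mutually consistent broad (4 MPP) and TSN (0.5 MPP) masks.

    The smooth geometry fields are sampled on an 8 MPP lattice and upsampled
    (tissue-geometry correlation lengths are hundreds of microns, far above
    the 8 um lattice), which keeps generation fast and memory-light on
    multi-millimetre extents.  Class-fraction thresholds are quantiles of the
    noise field, so realised fractions track the requested ones to within
    pixel discretisation.
    """
    rng = np.random.default_rng(spec.seed)
    gen_mpp = 8.0
    w_um, h_um = spec.extent_um
    w8, h8 = max(1, int(round(w_um / gen_mpp))), max(1, int(round(h_um / gen_mpp)))

    if spec.cancer_fraction <= 0:
        cancer8 = np.zeros((h8, w8), dtype=bool)
    elif spec.cancer_fraction >= 1:
        cancer8 = np.ones((h8, w8), dtype=bool)
    else:
        f8 = _smooth_field((h8, w8), spec.blob_scale_um / gen_mpp, rng)
        cancer8 = f8 >= np.quantile(f8, 1.0 - spec.cancer_fraction)
    cancer4 = np.repeat(np.repeat(cancer8, 2, axis=0), 2, axis=1)
    broad = LabelRaster(cancer4.astype(np.uint8), BROAD_MPP, dict(BROAD_CLASSES))

    tsn8 = np.zeros((h8, w8), dtype=np.uint8)
    if cancer8.any():
        part = _smooth_field((h8, w8), spec.tsn_scale_um / gen_mpp, rng)
        inside = part[cancer8]
        ft, fs, fn = spec.tsn_fractions
        q_t = np.quantile(inside, ft)
        q_ts = np.quantile(inside, ft + fs)
        tsn8[cancer8] = np.where(inside <= q_t, TSN_CLASSES["tumour"],
                                 np.where(inside <= q_ts, TSN_CLASSES["stroma"],
                                          TSN_CLASSES["necrosis"]))
    tsn_grid = np.repeat(np.repeat(tsn8, 16, axis=0), 16, axis=1)
    tsn = LabelRaster(tsn_grid, TSN_MPP, dict(TSN_CLASSES))
    return Layout(broad, tsn, spec)


def render_slide_rgb(layout: Layout, points: PointSet | None = None,
                     mpp: float = TIL_MPP, jitter: int = 3,
                     seed: int | None = None) -> np.ndarray:
    """Render the toy-palette RGB slide at ``mpp`` (default 0.25, i.e. 40x).

    TILs are drawn as dark disks in their compartment's TIL colour.  ``jitter``
    adds seeded uniform per-pixel colour noise so colour-rule backends are
    exercised on non-constant input.
    """
    grid = upsample_labels(layout.tsn, mpp).grid
    h, w = grid.shape
    lut = np.zeros((4, 3), dtype=np.uint8)
    lut[TSN_CLASSES["other"]] = PALETTE["background"]
    lut[TSN_CLASSES["tumour"]] = PALETTE["tumour"]
    lut[TSN_CLASSES["stroma"]] = PALETTE["stroma"]
    lut[TSN_CLASSES["necrosis"]] = PALETTE["necrosis"]
    rgb = lut[grid]
    del grid

    if points is not None and len(points):
        r_px = TIL_DISK_RADIUS_UM / mpp
        rr = int(np.ceil(r_px))
        dy, dx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        disk = (dx * dx + dy * dy) <= r_px * r_px
        comp = points.compartment
        if comp is None:
            comp = np.array(["tumour"] * len(points), dtype=object)
        for (x_um, y_um), c in zip(points.xy_um, comp):
            colour = PALETTE.get(f"til_{c}")
            if colour is None:
                continue
            cx, cy = int(x_um / mpp), int(y_um / mpp)
            r0, r1 = max(0, cy - rr), min(h, cy + rr + 1)
            c0, c1 = max(0, cx - rr), min(w, cx + rr + 1)
            sub = disk[r0 - (cy - rr): r1 - (cy - rr), c0 - (cx - rr): c1 - (cx - rr)]
            rgb[r0:r1, c0:c1][sub] = colour

    if jitter > 0:
        rng = np.random.default_rng(layout.spec.seed + 1 if seed is None else seed)
        # jitter in row blocks to keep the int16 intermediates small
        block = max(1, int(64e6 // max(1, w * 3)))
        for r0 in range(0, h, block):
            sub = rgb[r0:r0 + block]
            noise = rng.integers(-jitter, jitter + 1, size=sub.shape, dtype=np.int16)
            np.clip(sub.astype(np.int16) + noise, 0, 255, out=noise)
            rgb[r0:r0 + block] = noise.astype(np.uint8)
    return rgb


def _hardcore_thin(xy: np.ndarray, min_sep: float) -> np.ndarray:
    """Greedy first-come hard-core thinning; returns a boolean keep mask."""
    n = len(xy)
    keep = np.zeros(n, dtype=bool)
    if n == 0:
        return keep
    tree = cKDTree(xy)
    neighbours = tree.query_ball_point(xy, r=min_sep)
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        if removed[i]:
            continue
        keep[i] = True
        for j in neighbours[i]:
            if j > i:
                removed[j] = True
    return keep


def plant_tils(tsn_mask: LabelRaster, spec: PlantSpec) -> PointSet:
    """Plant a TIL point process on the tumour and stroma compartments.

    Homogeneous Poisson per compartment (intensity in points per mm^2 of that
    compartment), thinned to a hard-core minimum separation across *all*
    planted points.  Every point lies strictly inside a pixel of its
    compartment.  Emits a warning if thinning removes more than 10% of points
    (densities near the packing limit are no longer Poisson-like).
    """
    rng = np.random.default_rng(spec.seed)
    xs, ys, comps = [], [], []
    px_mm2 = (tsn_mask.mpp / 1000.0) ** 2
    ox, oy = tsn_mask.origin_um
    for comp, lam in (("tumour", spec.lambda_tumour), ("stroma", spec.lambda_stroma)):
        if lam <= 0:
            continue
        rows, cols = np.nonzero(tsn_mask.mask(comp))
        if rows.size == 0:
            continue
        area = rows.size * px_mm2
        n = rng.poisson(lam * area)
        if n == 0:
            continue
        pick = rng.integers(0, rows.size, size=n)
        u = rng.random((n, 2))
        xs.append((cols[pick] + u[:, 0]) * tsn_mask.mpp + ox)
        ys.append((rows[pick] + u[:, 1]) * tsn_mask.mpp + oy)
        comps.extend([comp] * n)
    if not xs:
        return PointSet.empty().with_compartment(np.array([], dtype=object))
    xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    comp_arr = np.array(comps, dtype=object)
    # random visit order for the hard-core thinning, seeded
    order = rng.permutation(len(xy))
    keep = _hardcore_thin(xy[order], spec.min_separation_um)
    if keep.size and (1.0 - keep.mean()) > 0.10:
        warnings.warn(
            f"hard-core thinning removed {100 * (1 - keep.mean()):.1f}% of points; "
            "planted density is saturating at this min separation", stacklevel=2)
    sel = order[keep]
    return PointSet(xy[sel], np.ones(sel.size), comp_arr[sel])


def render_heatmap(points: PointSet, spec: HeatmapSpec, extent_px: tuple[int, int],
                   amplitude_range: tuple[float, float] = (0.6, 1.0),
                   n_decoys: int = 0,
                   decoy_amplitude: tuple[float, float] = (0.05, 0.30),
                   noise_sigma: float = 0.0,
                   seed: int = 0) -> np.ndarray:
    """Simulate a TIL model's output heatmap for planted points.

    True points are rendered as Gaussians with peaks drawn from
    ``amplitude_range``; ``n_decoys`` spurious low-amplitude blobs (peaks from
    ``decoy_amplitude``, below the 0.35 gate by default) and additive Gaussian
    noise emulate model uncertainty.  Output is clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    w, h = extent_px
    heat = np.zeros((h, w))
    if len(points):
        amps = rng.uniform(*amplitude_range, size=len(points))
        for amp in np.unique(amps):
            sub = points.select(amps == amp)
            layer = encode_points(sub, extent_px, spec)
            np.maximum(heat, amp * layer, out=heat)
    if n_decoys > 0:
        dx = rng.uniform(0, w * spec.mpp, size=n_decoys)
        dy = rng.uniform(0, h * spec.mpp, size=n_decoys)
        amps = rng.uniform(*decoy_amplitude, size=n_decoys)
        for x, y, a in zip(dx, dy, amps):
            layer = encode_points(PointSet(np.array([[x, y]])), extent_px, spec)
            np.maximum(heat, a * layer, out=heat)
    if noise_sigma > 0:
        heat = heat + rng.normal(0.0, noise_sigma, size=heat.shape)
    return np.clip(heat, 0.0, 1.0)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a survival cohort with a planted TIL effect.

    Returns a patient table with survival time (days), event indicator, the
    usual clinicopathological covariates (independent of outcome here), the
    continuous AI iTIL score, and the true (planted) risk group.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    score = np.exp(rng.normal(np.log(spec.score_median), spec.score_sigma, size=n))
    low_til = score < spec.true_cutoff
    hazard = spec.baseline_hazard * np.where(low_til, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    time_days = np.maximum(1, np.rint(np.minimum(t_event, t_cens))).astype(int)
    event = (t_event <= t_cens).astype(int)

    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "time_days": time_days,
        "event": event,
        "endpoint": "RFS",
        "stage": rng.choice(["II", "III"], size=n),
        "age_decades": np.round(rng.normal(7.0, 1.2, size=n), 1),
        "gender": rng.choice(["female", "male"], size=n),
        "site": rng.choice(["proximal", "distal"], size=n),
        "t4": rng.random(n) < 0.2,
        "n_stage2": rng.random(n) < 0.25,
        "nodes_lt12": rng.random(n) < 0.15,
        "grade_high": rng.random(n) < 0.3,
        "lvi": rng.random(n) < 0.3,
        "emvi": rng.random(n) < 0.2,
        "mmr_proficient": rng.random(n) < 0.85,
        "adjuvant_chemo": rng.random(n) < 0.5,
        "ai_itil_score": score,
    })
    df["til_class"] = np.where(low_til, "TIL-Low", "TIL-High")
    return df
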