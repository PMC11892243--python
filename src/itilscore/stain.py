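"""Macenko stain normalisation for H&E tiles.

Standardises stain appearance across scanners/labs before model inference.
The method works in optical density (OD) space, ``OD = -log10(I / I0)``:
H&E pixels lie close to a 2-D plane spanned by the haematoxylin and eosin
absorption vectors.  The two stain vectors are estimated as robust angular
extremes of the tissue pixels projected onto that plane (singular/eigen
directions of the OD covariance), per-pixel stain concentrations are solved
by least squares, rescaled so that a high percentile matches a reference
maximum, and the image is re-composited with the reference stain matrix.

Defaults follow common practice: OD floor beta = 0.15 to drop background,
angular percentiles 1/99, concentration scaling at the 99th percentile.
The reference stain matrix is the widely used H&E basis from the original
method's published implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StainReference",
    "StainEstimationError",
    "DEFAULT_REFERENCE",
    "estimate_stain_matrix",
    "macenko_normalize",
]

I0 = 255.0  # transmitted-light intensity of a stain-free pixel (8-bit white)


class StainEstimationError(RuntimeError):
    """Raised when stain vectors cannot be estimated (blank tile, degenerate OD)."""


@dataclass(frozen=True)
class StainReference:
    """Target stain basis: columns of ``stain_matrix`` are unit OD vectors (H, E)."""

    stain_matrix: np.ndarray          # (3, 2), column-normalised, nonnegative
    max_concentrations: np.ndarray    # (2,), percentile-based scale for (H, E)

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        c = np.asarray(self.max_concentrations, dtype=float)
        if m.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        if np.any(m < -1e-9):
            raise ValueError("stain vectors must be nonnegative in OD space")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit-norm")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "max_concentrations", c)


# Classic H&E reference basis and concentration maxima.
DEFAULT_REFERENCE = StainReference(
    stain_matrix=np.array([[0.5626, 0.2159],
                           [0.7201, 0.8012],
                           [0.4062, 0.5581]])
    / np.linalg.norm([[0.5626, 0.2159], [0.7201, 0.8012], [0.4062, 0.5581]], axis=0),
    max_concentrations=np.array([1.9705, 1.0308]),
)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel; 8-bit input, zeros clamped to 1."""
    return -np.log10(np.maximum(rgb.astype(np.float64), 1.0) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(I0 * np.power(10.0, -od)), 0, 255).astype(np.uint8)


def estimate_stain_matrix(rgb: np.ndarray, beta_od_floor: float = 0.15,
                          angular_percentile: float = 1.0) -> np.ndarray:
    """Estimate the (3, 2) H&E stain matrix of an RGB tile (Macenko).

    Raises
    ------
    StainEstimationError
        If there are too few tissue pixels above the OD floor or the OD cloud
        is degenerate (e.g. single-colour tile).
    """
    od = rgb_to_od(rgb).reshape(-1, 3)
    tissue = od[~np.any(od < beta_od_floor, axis=1)]
    if tissue.shape[0] < 16:
        raise StainEstimationError(
            f"only {tissue.shape[0]} tissue pixels above OD floor {beta_od_floor}")

    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-12:  # OD cloud has no plane: single stain direction at best
        raise StainEstimationError("degenerate OD covariance; cannot span a stain plane")
    plane = evecs[:, [-1, -2]]           # top-2 eigenvectors, columns
    # Orient the plane so projections are mostly positive (OD is nonnegative).
    proj = tissue @ plane
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[:, k] = -plane[:, k]
            proj[:, k] = -proj[:, k]

    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angular_percentile)
    hi = np.percentile(phi, 100.0 - angular_percentile)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    v1 = np.clip(v1, 0, None)
    v2 = np.clip(v2, 0, None)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise StainEstimationError("degenerate angular extremes")
    v1, v2 = v1 / n1, v2 / n2
    # Haematoxylin absorbs more red light than eosin: larger R-channel OD first.
    he = np.column_stack([v1, v2] if v1[0] >= v2[0] else [v2, v1])
    return he


def _concentrations(od_flat: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares stain concentrations, shape (2, N)."""
    sol, *_ = np.linalg.lstsq(stain_matrix, od_flat.T, rcond=None)
    return sol


def macenko_normalize(rgb_tile: np.ndarray,
                      reference: StainReference = DEFAULT_REFERENCE,
                      io_percentile: float = 99.0,
                      beta_od_floor: float = 0.15,
                      angular_percentile: float = 1.0) -> np.ndarray:
    """Normalise an 8-bit RGB H&E tile to the reference stain appearance.

    Parameters
    ----------
    rgb_tile : (H, W, 3) uint8 image.
    reference : target stain basis and concentration maxima.
    io_percentile : percentile of per-stain concentration used as the tile's
        "maximum" when rescaling to ``reference.max_concentrations``.
    beta_od_floor : OD threshold below which pixels count as background.
    angular_percentile : robust percentile for the angular extremes.

    Returns
    -------
    (H, W, 3) uint8 image re-composited in the reference stains.

    Raises
    ------
    StainEstimationError
        For blank/background-only tiles or degenerate OD distributions; the
        caller may record this as a slide-level quality flag.
    """
    rgb_tile = np.asarray(rgb_tile)
    if rgb_tile.ndim != 3 or rgb_tile.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    he = estimate_stain_matrix(rgb_tile, beta_od_floor, angular_percentile)

    od = rgb_to_od(rgb_tile).reshape(-1, 3)
    conc = _concentrations(od, he)                       # (2, N)
    max_c = np.percentile(np.clip(conc, 0, None), io_percentile, axis=1)
    max_c = np.maximum(max_c, 1e-6)
    conc *= (reference.max_concentrations / max_c)[:, None]
    od_norm = (reference.stain_matrix @ conc).T.reshape(rgb_tile.shape)
    return od_to_rgb(od_norm)
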