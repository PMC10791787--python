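"""Lysosomal-burden quantification from immunofluorescence channels.

Pipeline: rolling-ball background subtraction per channel (10 px for the
microglial Iba1 and lysosomal CD68 channels, 80 px for Aβ), thresholding to
binary masks, and the percentage of Iba1+ area that is also CD68+ — the
standard phagocytic-capacity proxy. Cells are classed as plaque-associated
or plaque-distant by distance to the nearest Aβ-mask pixel (50 µm cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

__all__ = [
    "ChannelImage",
    "CoverageParams",
    "CoverageResult",
    "rolling_ball_subtract",
    "make_mask",
    "coverage",
    "classify_proximity",
]


@dataclass
class ChannelImage:
    pixels: np.ndarray
    channel: str                    # "Iba1" | "CD68" | "Abeta"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("expected a 2D grayscale image")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class CoverageParams:
    ball_radius_px: int = 10            # 80 for the Aβ channel
    threshold_method: str = "otsu"      # "otsu" | "fixed"
    fixed_threshold: float | None = None
    plaque_distance_cutoff_um: float = 50.0

    def __post_init__(self) -> None:
        if self.ball_radius_px < 1:
            raise ValueError("ball_radius_px must be >= 1")
        if self.plaque_distance_cutoff_um <= 0:
            raise ValueError("plaque_distance_cutoff_um must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


@dataclass
class CoverageResult:
    iba1_area_px: int
    overlap_area_px: int
    coverage_pct: float
    proximity_class: str | None = None
    undefined: bool = False            # empty Iba1 mask


def rolling_ball_subtract(img: ChannelImage, radius_px: int) -> ChannelImage:
    """Rolling-ball background subtraction.

    The background is the grayscale morphological opening of the image with
    a ball (disk) structuring element of the given radius — the morphological
    formulation of the classic rolling-ball estimate; the result is the image
    minus that background, clipped at zero.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if radius_px * 2 + 1 > min(img.pixels.shape):
        warnings.warn("rolling-ball radius exceeds image half-extent; "
                      "background estimate will be coarse", stacklevel=2)
    background = opening(img.pixels, footprint=disk(radius_px))
    out = np.clip(img.pixels - background, 0.0, None)
    return ChannelImage(pixels=out, channel=img.channel,
                        pixel_size_um=img.pixel_size_um)


def make_mask(img: ChannelImage, params: CoverageParams | None = None
              ) -> np.ndarray:
    """Threshold a background-subtracted channel into a binary mask.

    Otsu's method by default; a fixed intensity can be forced. Pixels at or
    above the threshold are foreground. A flat image cannot be Otsu-split and
    yields an empty mask with a warning.
    """
    params = params or CoverageParams()
    px = img.pixels
    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        if px.min() == px.max():
            warnings.warn("image has a single intensity; Otsu undefined, "
                          "returning empty mask", stacklevel=2)
            return np.zeros(px.shape, dtype=bool)
        thr = threshold_otsu(px)
    return px >= thr


def coverage(iba1_mask: np.ndarray, cd68_mask: np.ndarray) -> CoverageResult:
    """Percentage of the Iba1+ area that is also CD68+."""
    iba1_mask = np.asarray(iba1_mask, dtype=bool)
    cd68_mask = np.asarray(cd68_mask, dtype=bool)
    if iba1_mask.shape != cd68_mask.shape:
        raise ValueError("masks must share shape")
    iba1_area = int(iba1_mask.sum())
    overlap = int((iba1_mask & cd68_mask).sum())
    if iba1_area == 0:
        return CoverageResult(0, 0, float("nan"), undefined=True)
    return CoverageResult(iba1_area, overlap, 100.0 * overlap / iba1_area)


def classify_proximity(roi_centroid_um: tuple[float, float],
                       plaque_mask: np.ndarray, pixel_size_um: float,
                       cutoff_um: float = 50.0) -> str:
    """Label an ROI as at_plaque or away_from_plaque by Euclidean distance
    from its centroid to the nearest plaque pixel (µm). An empty plaque mask
    classifies everything as away_from_plaque (with a warning)."""
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    ys, xs = np.nonzero(plaque_mask)
    if ys.size == 0:
        warnings.warn("empty plaque mask; classifying as away_from_plaque",
                      stacklevel=2)
        return "away_from_plaque"
    cy, cx = roi_centroid_um
    d = np.sqrt((ys * pixel_size_um - cy) ** 2 + (xs * pixel_size_um - cx) ** 2)
    return "at_plaque" if float(d.min()) <= cutoff_um else "away_from_plaque"
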