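"""Core spatial readouts: radial profiles, center/edge region means, fold change.

The radial profile bins pixel intensities by normalized radius r in [0, 1]
(equal-width, half-open bins, last bin closed) and reports per-bin mean,
standard deviation and pixel count.  Region quantification places small
square sampling ROIs near the island center (r = 0.1 by default) and near
the edge (r = 0.85) and averages fluorescence inside each, mirroring the
manual center-vs-edge workflow; the center-to-edge fold change is the ratio
of background-corrected region means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ArithmeticDomainError,
    EmptyInputError,
    ParameterError,
    PlacementError,
    QuantificationError,
)
from .geometry import IslandROI, PolarPixels
from .io import MicropatternImage

NORMALIZATIONS = ("raw", "max", "mean")


@dataclass
class RadialProfile:
    """Binned mean intensity over normalized radius.

    Empty bins carry NaN in ``mean_intensity``/``sd_intensity`` and 0 in
    ``pixel_count``; they are never imputed.  ``sd_intensity`` is the
    population standard deviation of member pixels.  Normalization rescales
    the mean (and sd, to preserve relative dispersion) by the curve maximum
    ("max") or the pixel-weighted grand mean ("mean").
    """

    bin_edges: np.ndarray
    mean_intensity: np.ndarray
    sd_intensity: np.ndarray
    pixel_count: np.ndarray
    normalization: str = "raw"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.mean_intensity,
                "sd": self.sd_intensity,
                "n": self.pixel_count,
            }
        )


@dataclass
class SamplingSquare:
    """An axis-aligned square sampling ROI, in pixel coordinates."""

    center: tuple[float, float]
    side: float

    @property
    def corners(self) -> np.ndarray:
        cx, cy = self.center
        h = self.side / 2
        return np.array(
            [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
        )


@dataclass
class RegionQuant:
    """Mean fluorescence of one island region sampled by several square ROIs."""

    region: str  # "center" | "edge"
    roi_centers: list[tuple[float, float]]
    roi_side: float
    per_roi_mean: list[float]
    region_mean: float = field(init=False)

    def __post_init__(self):
        self.region_mean = float(np.mean(self.per_roi_mean))


def radial_profile(
    pixels: PolarPixels, n_bins: int = 50, normalization: str = "raw"
) -> RadialProfile:
    """Bin polar pixels into an equal-width radial intensity profile.

    Bins are half-open [lo, hi) over [0, 1], with the last bin closed so
    that r = 1 is included.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if normalization not in NORMALIZATIONS:
        raise ParameterError(f"normalization must be one of {NORMALIZATIONS}")
    if len(pixels) == 0:
        raise EmptyInputError("no pixels to profile")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((pixels.r * n_bins).astype(int), n_bins - 1)
    count = np.bincount(idx, minlength=n_bins).astype(int)
    s1 = np.bincount(idx, weights=pixels.intensity, minlength=n_bins)
    s2 = np.bincount(idx, weights=pixels.intensity**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 0, s2 / np.maximum(count, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0, None))

    if normalization == "max":
        scale = np.nanmax(mean)
    elif normalization == "mean":
        scale = s1.sum() / count.sum()  # pixel-weighted grand mean
    else:
        scale = 1.0
    if normalization != "raw":
        if scale == 0:
            raise ArithmeticDomainError("cannot normalize an all-zero profile")
        mean = mean / scale
        sd = sd / scale
    return RadialProfile(
        bin_edges=edges,
        mean_intensity=mean,
        sd_intensity=sd,
        pixel_count=count,
        normalization=normalization,
    )


def place_region_rois(
    roi: IslandROI,
    region: str,
    n: int = 5,
    roi_side: float = 0.1,
    start_angle: float = 0.0,
    center_r: float = 0.1,
    edge_r: float = 0.85,
) -> list[SamplingSquare]:
    """Place ``n`` square sampling ROIs in the center or edge region.

    Center ROIs sit on a small circle at normalized radius ``center_r``
    (or on the centroid itself when n = 1); edge ROIs are equally spaced in
    angle at ``edge_r``.  The square side is ``roi_side`` times the local
    boundary distance R(theta), so squares scale with the island.  Placement
    is deterministic given ``start_angle``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if region not in ("center", "edge"):
        raise ParameterError(f"region must be 'center' or 'edge', got {region!r}")
    if region == "center":
        r_place = 0.0 if n == 1 else center_r
    else:
        r_place = edge_r

    cx, cy = roi.centroid
    angles = start_angle + 2 * np.pi * np.arange(n) / n
    squares = []
    for th in angles:
        R = float(roi.boundary_distance(th)[0])
        px = cx + r_place * R * np.cos(th)
        py = cy + r_place * R * np.sin(th)
        sq = SamplingSquare(center=(float(px), float(py)), side=roi_side * R)
        inside = roi.contains(sq.corners[:, 0], sq.corners[:, 1])
        if not np.all(inside):
            raise PlacementError(
                f"{region} ROI at angle {np.degrees(th):.1f} deg extends outside "
                f"the island boundary; reduce roi_side (= {roi_side})"
            )
        squares.append(sq)
    return squares


def quantify_regions(
    image: MicropatternImage, squares: list[SamplingSquare], region: str = ""
) -> RegionQuant:
    """Average fluorescence inside each sampling square.

    A pixel belongs to a square when its center lies within the square's
    extent.  ``region_mean`` is the unweighted mean of the per-ROI means.
    """
    rows, cols = image.shape
    per_roi = []
    for sq in squares:
        cx, cy = sq.center
        h = sq.side / 2
        x0, x1 = int(np.ceil(cx - h)), int(np.floor(cx + h))
        y0, y1 = int(np.ceil(cy - h)), int(np.floor(cy + h))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, cols - 1), min(y1, rows - 1)
        if x1 < x0 or y1 < y0:
            raise QuantificationError(
                f"sampling square at {sq.center} contains no pixel centers"
            )
        per_roi.append(float(image.pixels[y0 : y1 + 1, x0 : x1 + 1].mean()))
    return RegionQuant(
        region=region,
        roi_centers=[sq.center for sq in squares],
        roi_side=squares[0].side if squares else 0.0,
        per_roi_mean=per_roi,
    )


def fold_change(
    edge: RegionQuant, center: RegionQuant, background: float = 0.0
) -> float:
    """Edge-to-center ratio of background-corrected region means."""
    denom = center.region_mean - background
    if denom <= 0:
        raise ArithmeticDomainError(
            f"center mean ({center.region_mean}) minus background "
            f"({background}) must be positive"
        )
    return (edge.region_mean - background) / denom


def estimate_background(image: MicropatternImage, roi: IslandROI) -> float:
    """Median intensity outside the island boundary (a scalar per image)."""
    mask = roi.interior_mask(image.shape)
    outside = image.pixels[~mask]
    if outside.size == 0:
        raise EmptyInputError("island fills the frame; no outside pixels")
    return float(np.median(outside))
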