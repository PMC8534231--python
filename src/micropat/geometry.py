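"""Island geometry: locate the micropattern, build its normalized polar frame.

The measurement frame is centered on the island centroid.  Every pixel gets
an angle theta = atan2(y - cy, x - cx) and a normalized radius
r = d / R(theta), where d is the Euclidean distance to the centroid and
R(theta) is the distance from the centroid to the island boundary along the
same direction.  r = 0 at the center, r = 1 on the edge, for circular and
irregular (polygonal) islands alike: normalization is direction-dependent,
so the true edge always maps to r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import filters, measure

from .errors import (
    AmbiguityError,
    DetectionError,
    GeometryError,
    ValidationError,
)
from .io import MicropatternImage


@dataclass
class IslandROI:
    """Centroid plus boundary of one micropattern island.

    ``boundary_kind`` is ``"circle"`` (with ``radius`` in px) or
    ``"polygon"`` (with ``vertices`` as an (n, 2) array of (x, y) pixel
    coordinates, implicitly closed).  ``source`` records whether the ROI was
    auto-detected or supplied by the user; a manual ROI always overrides
    detection in the pipeline.
    """

    centroid: tuple[float, float]
    boundary_kind: str  # "circle" | "polygon"
    radius: float | None = None
    vertices: np.ndarray | None = None
    source: str = "auto"

    def __post_init__(self):
        self.centroid = (float(self.centroid[0]), float(self.centroid[1]))
        if self.boundary_kind == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValidationError("circle ROI requires radius > 0")
        elif self.boundary_kind == "polygon":
            v = np.asarray(self.vertices, dtype=np.float64)
            if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
                raise ValidationError("polygon ROI requires an (n>=3, 2) vertex array")
            if np.allclose(v[0], v[-1]):
                v = v[:-1]
            poly = Polygon(v)
            if not poly.is_valid or not poly.is_simple:
                raise ValidationError("polygon ROI boundary must be simple")
            if not poly.contains(Point(self.centroid)):
                raise ValidationError("centroid must lie strictly inside the boundary")
            self.vertices = v
        else:
            raise ValidationError(f"unknown boundary kind {self.boundary_kind!r}")

    # -- geometry ---------------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon of the boundary (circles as 256-gon approximations)."""
        if self.boundary_kind == "circle":
            return Point(self.centroid).buffer(self.radius, quad_segs=64)
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        if self.boundary_kind == "circle":
            return float(np.pi * self.radius**2)
        return Polygon(self.vertices).area

    def boundary_distance(self, theta) -> np.ndarray:
        """Distance R(theta) from the centroid to the boundary along each angle.

        Constant for circles; exact ray/edge intersection for polygons.
        """
        theta = np.atleast_1d(np.asarray(theta, dtype=np.float64))
        if self.boundary_kind == "circle":
            return np.full(theta.shape, float(self.radius))
        return _ray_polygon_distance(self.vertices, self.centroid, theta)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-boundary test (pixel centers strictly inside)."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.boundary_kind == "circle":
            cx, cy = self.centroid
            return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2
        return shapely.contains_xy(Polygon(self.vertices), x, y)

    def interior_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the boundary."""
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        return self.contains(xx.ravel(), yy.ravel()).reshape(rows, cols)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "centroid": list(self.centroid),
            "kind": self.boundary_kind,
            "source": self.source,
        }
        if self.boundary_kind == "circle":
            d["radius"] = self.radius
        else:
            d["vertices"] = self.vertices.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IslandROI":
        return cls(
            centroid=tuple(d["centroid"]),
            boundary_kind=d["kind"],
            radius=d.get("radius"),
            vertices=d.get("vertices"),
            source=d.get("source", "manual"),
        )


@dataclass
class PolarPixels:
    """Pixels of one island mapped to the normalized polar frame.

    Column-parallel arrays: ``r`` in [0, 1], ``theta`` in [-pi, pi),
    ``intensity`` in fluorescence units, plus the originating integer pixel
    coordinates ``x``/``y``.
    """

    r: np.ndarray
    theta: np.ndarray
    intensity: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self):
        return len(self.r)


def _ray_polygon_distance(vertices, centroid, theta):
    """Exact distance from ``centroid`` to the polygon boundary along ``theta``.

    Solves the ray/segment intersection C + t*u = P1 + s*(P2 - P1) for every
    edge and keeps the smallest positive t.  The centroid is inside the
    (simple) polygon, so every ray hits the boundary.
    """
    cx, cy = centroid
    ux, uy = np.cos(theta), np.sin(theta)
    best = np.full(theta.shape, np.inf)
    v = np.asarray(vertices, dtype=np.float64)
    n = len(v)
    eps = 1e-12
    for i in range(n):
        p1 = v[i]
        p2 = v[(i + 1) % n]
        ex, ey = p2[0] - p1[0], p2[1] - p1[1]
        wx, wy = p1[0] - cx, p1[1] - cy
        denom = ux * ey - uy * ex
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (wx * ey - wy * ex) / denom
            s = (wx * uy - wy * ux) / denom
        valid = (np.abs(denom) > eps) & (t > eps) & (s >= -1e-9) & (s <= 1 + 1e-9)
        np.minimum(best, np.where(valid, t, np.inf), out=best)
    if np.any(np.isinf(best)):
        raise GeometryError(
            "a ray from the centroid missed the polygon boundary "
            "(centroid outside polygon?)"
        )
    return best


def polar_coordinates(roi: IslandROI, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Normalized polar coordinates (r, theta) of arbitrary points.

    r = d / R(theta); r is 0 at the centroid and 1 on the boundary.  Points
    at the exact centroid get theta = 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    cx, cy = roi.centroid
    dx, dy = x - cx, y - cy
    d = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)  # [-pi, pi]
    theta = np.where(theta >= np.pi, theta - 2 * np.pi, theta)
    R = roi.boundary_distance(theta)
    with np.errstate(invalid="ignore"):
        r = np.where(d == 0, 0.0, d / R)
    return r, theta


def to_polar(image: MicropatternImage, roi: IslandROI) -> PolarPixels:
    """Map every pixel whose center lies inside the ROI to the polar frame.

    Each interior pixel appears exactly once; pixels outside the boundary
    are excluded.
    """
    mask = roi.interior_mask(image.shape)
    ys, xs = np.nonzero(mask)
    r, theta = polar_coordinates(roi, xs.astype(float), ys.astype(float))
    return PolarPixels(
        r=r,
        theta=theta,
        intensity=image.pixels[ys, xs],
        x=xs,
        y=ys,
    )


def detect_island(
    image: MicropatternImage,
    min_area_fraction: float = 0.05,
    smooth_sigma: float = 2.0,
    circularity_cutoff: float = 0.85,
    simplify_tolerance: float = 1.0,
) -> IslandROI:
    """Auto-detect the single bright island in an image.

    The image is Gaussian-smoothed (``smooth_sigma`` px), Otsu-thresholded,
    and the largest connected foreground component (holes filled) becomes
    the island mask.  The centroid is the intensity-unweighted centroid of
    the mask.  If the mask circularity 4*pi*A/P**2 is at least
    ``circularity_cutoff``, the boundary is a circle of equivalent-area
    radius sqrt(A/pi); otherwise the traced and simplified mask outline.

    Raises
    ------
    DetectionError
        No foreground component covers ``min_area_fraction`` of the frame.
    AmbiguityError
        A second component has at least half the area of the largest.
    """
    pix = image.pixels
    if np.ptp(pix) == 0:
        raise DetectionError("image is constant; no island to detect")
    smoothed = ndimage.gaussian_filter(pix, sigma=smooth_sigma)
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    labels, n_comp = ndimage.label(fg)
    if n_comp == 0:
        raise DetectionError("no foreground found after thresholding")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(areas)[::-1]
    min_area = min_area_fraction * pix.size
    if areas[order[0]] < min_area:
        raise DetectionError(
            f"largest component ({areas[order[0]]:.0f} px) below "
            f"min_area_fraction ({min_area:.0f} px)"
        )
    if len(order) > 1 and areas[order[1]] >= 0.5 * areas[order[0]]:
        cand = sorted(areas[areas >= 0.5 * areas[order[0]]], reverse=True)
        raise AmbiguityError(
            f"multiple comparable foreground components, areas {cand}",
            candidate_areas=cand,
        )
    mask = ndimage.binary_fill_holes(labels == order[0] + 1)

    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()), float(ys.mean()))
    area = float(mask.sum())
    perim = measure.perimeter_crofton(mask, directions=4)
    circ = 4 * np.pi * area / perim**2 if perim > 0 else 0.0
    if circ >= circularity_cutoff:
        return IslandROI(
            centroid=centroid,
            boundary_kind="circle",
            radius=float(np.sqrt(area / np.pi)),
            source="auto",
        )
    contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len)  # (row, col) order
    verts = np.column_stack([outline[:, 1], outline[:, 0]])  # -> (x, y)
    poly = Polygon(verts).simplify(simplify_tolerance, preserve_topology=True)
    return IslandROI(
        centroid=centroid,
        boundary_kind="polygon",
        vertices=np.asarray(poly.exterior.coords[:-1]),
        source="auto",
    )
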