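"""Synthetic micropattern image generator with paired ground truth.

Emulates widefield fluorescence images of circular micropatterned tumor-cell
islands: a bright disc on a dark background whose intensity follows a
prescribed radial function (flat, linear, edge-high or center-high sigmoid,
or step), optional Gaussian cell blobs at rejection-sampled positions,
optional membrane-like junction ridges along a Voronoi tessellation of the
cell centers (a cobblestone-like monolayer geometry), and a mixed
Poisson-Gaussian camera noise model.  Every stochastic draw flows through a
single seeded generator in a documented order, so identical spec + seed
gives a bit-identical image.

Default geometry is desk scale: a 512x512 px frame with an island radius of
200 px, a scaled stand-in for real 500 um - 2 mm patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point
from shapely.ops import voronoi_diagram

from .errors import PackingError, ParameterError, ValidationError
from .geometry import IslandROI, polar_coordinates
from .io import CellContour, ContourSet, MicropatternImage

# ---------------------------------------------------------------------------
# radial intensity models


@dataclass(frozen=True)
class RadialModel:
    """A 1-D intensity model I(r) over normalized radius r in [0, 1].

    Kinds and parameters:

    - ``flat``: c — constant c
    - ``linear``: a, b — a + b*r
    - ``sigmoid_edge_high``: lo, hi, r0, k — lo + (hi-lo)/(1+exp(-k*(r-r0)))
    - ``sigmoid_center_high``: hi, lo, r0, k — hi + (lo-hi)/(1+exp(-k*(r-r0)))
    - ``step``: inner, outer, r_cut — inner for r < r_cut, else outer
    """

    kind: str
    params: tuple[float, ...]

    _ARITY = {
        "flat": 1,
        "linear": 2,
        "sigmoid_edge_high": 4,
        "sigmoid_center_high": 4,
        "step": 3,
    }

    def __post_init__(self):
        if self.kind not in self._ARITY:
            raise ParameterError(f"unknown radial model kind {self.kind!r}")
        if len(self.params) != self._ARITY[self.kind]:
            raise ParameterError(
                f"radial model {self.kind!r} takes {self._ARITY[self.kind]} "
                f"parameters, got {len(self.params)}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=np.float64)
        p = self.params
        if self.kind == "flat":
            return np.full(r.shape, p[0])
        if self.kind == "linear":
            return p[0] + p[1] * r
        if self.kind == "sigmoid_edge_high":
            lo, hi, r0, k = p
            return lo + (hi - lo) / (1.0 + np.exp(-k * (r - r0)))
        if self.kind == "sigmoid_center_high":
            hi, lo, r0, k = p
            return hi + (lo - hi) / (1.0 + np.exp(-k * (r - r0)))
        inner, outer, r_cut = p
        return np.where(r < r_cut, inner, outer)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d) -> "RadialModel":
        return cls(kind=d["kind"], params=tuple(d["params"]))


# ---------------------------------------------------------------------------
# spec and ground truth


@dataclass
class CellField:
    """Planted cell blobs: isotropic Gaussians at minimum-separation centers."""

    n: int = 50
    min_separation: float = 16.0
    blob_sigma: float = 4.0
    amplitude: float = 100.0
    edge_margin: float | None = None  # keep-out from the island edge; default blob_sigma


@dataclass
class JunctionModel:
    """Membrane-like ridges along the Voronoi tessellation of the cell centers."""

    ridge_sigma: float = 2.0  # Gaussian cross-section sigma, px
    ridge_amplitude: float = 200.0


@dataclass
class NoiseModel:
    """Mixed camera noise: Poisson shot noise, then additive Gaussian read noise."""

    poisson: bool = False
    gaussian_sd: float = 0.0


@dataclass
class SyntheticSpec:
    """Full parameterization of one simulated micropattern image.

    The default radial model is an edge-high sigmoid whose edge(r=0.85) to
    center(r=0.1) intensity ratio is very close to 3, the contrast scale
    typical of mitochondrial-membrane-potential gradients across confined
    tumor islands; its peak intensity of 400 counts puts the Poisson-limited
    peak SNR at sqrt(400) = 20, a realistic widefield regime.
    """

    image_size: tuple[int, int] = (512, 512)  # (rows, cols)
    island_center: tuple[float, float] = (255.5, 255.5)
    island_radius: float = 200.0
    radial_model: RadialModel = field(
        default_factory=lambda: RadialModel(
            "sigmoid_edge_high", (400.0 / 3.0, 400.0, 0.6, 20.0)
        )
    )
    cells: CellField | None = None
    junction_model: JunctionModel | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    background: float = 10.0
    bit_depth: int = 16
    seed: int = 0
    # sampling radii at which the planted fold change is defined
    center_r: float = 0.1
    edge_r: float = 0.85

    def __post_init__(self):
        if self.island_radius <= 0:
            raise ParameterError("island_radius must be > 0")
        if self.background < 0:
            raise ParameterError("background must be >= 0")
        if self.cells is not None and self.cells.n > 0:
            c = self.cells
            if c.amplitude < 0:
                raise ParameterError("cell amplitude must be >= 0")
            if c.min_separation < 2 * c.blob_sigma:
                raise ParameterError(
                    "min_separation must be >= 2*blob_sigma for resolvable blobs"
                )


@dataclass
class GroundTruth:
    """Everything planted into a synthetic image, for oracle-based testing."""

    island: IslandROI
    radial_model: RadialModel
    cell_centers: np.ndarray  # (n, 2) of (x, y)
    cell_contours: ContourSet | None
    junction_segments: list[tuple[tuple[float, float], tuple[float, float]]]
    planted_fold_change: float


# ---------------------------------------------------------------------------
# generation


def generate(spec: SyntheticSpec) -> tuple[MicropatternImage, GroundTruth]:
    """Render a synthetic micropattern image and its ground truth.

    Stages, in fixed order (all randomness from one generator seeded by
    ``spec.seed``): island radial field, cell centers, cell blobs, junction
    ridges, Poisson resampling, additive Gaussian noise, clip and quantize
    to ``bit_depth``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    island = IslandROI(
        centroid=spec.island_center,
        boundary_kind="circle",
        radius=spec.island_radius,
        source="manual",
    )

    yy, xx = np.mgrid[0:rows, 0:cols]
    cx, cy = spec.island_center
    d = np.hypot(xx - cx, yy - cy)
    inside = d <= spec.island_radius
    r = np.where(inside, d / spec.island_radius, 0.0)

    img = np.full((rows, cols), float(spec.background))
    img[inside] += spec.radial_model(r[inside])

    centers = np.empty((0, 2))
    contours = None
    segments: list = []
    if spec.cells is not None and spec.cells.n > 0:
        centers = _sample_centers(spec, rng)
        img += _render_blobs(
            (rows, cols), centers, spec.cells.blob_sigma, spec.cells.amplitude
        )
        if spec.junction_model is not None:
            contours, segments = _tessellate(centers, island)
            img += _render_ridges(
                (rows, cols),
                segments,
                spec.junction_model.ridge_amplitude,
                spec.junction_model.ridge_sigma,
            )

    if spec.noise.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.noise.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise.gaussian_sd, img.shape)
    img = np.clip(np.rint(img), 0, 2**spec.bit_depth - 1)

    fc = float(
        spec.radial_model(np.array(spec.edge_r))
        / spec.radial_model(np.array(spec.center_r))
    )
    truth = GroundTruth(
        island=island,
        radial_model=spec.radial_model,
        cell_centers=centers,
        cell_contours=contours,
        junction_segments=segments,
        planted_fold_change=fc,
    )
    image = MicropatternImage(pixels=img, bit_depth=spec.bit_depth)
    return image, truth


def _sample_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centers inside the island at min separation."""
    c = spec.cells
    margin = c.edge_margin if c.edge_margin is not None else c.blob_sigma
    r_max = spec.island_radius - margin
    if r_max <= 0:
        raise PackingError("edge margin leaves no room inside the island")
    cx, cy = spec.island_center
    centers: list[np.ndarray] = []
    budget = 1000 * c.n
    attempts = 0
    while len(centers) < c.n:
        if attempts >= budget:
            raise PackingError(
                f"could not place {c.n} cells at separation "
                f"{c.min_separation} within {budget} attempts"
            )
        attempts += 1
        rr = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = np.array([cx + rr * np.cos(th), cy + rr * np.sin(th)])
        if all(np.hypot(*(p - q)) >= c.min_separation for q in centers):
            centers.append(p)
    return np.vstack(centers)


def _render_blobs(shape, centers, sigma, amplitude) -> np.ndarray:
    rows, cols = shape
    out = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for x0, y0 in centers:
        xi0, xi1 = max(int(x0) - half, 0), min(int(x0) + half + 1, cols)
        yi0, yi1 = max(int(y0) - half, 0), min(int(y0) + half + 1, rows)
        yy, xx = np.mgrid[yi0:yi1, xi0:xi1]
        out[yi0:yi1, xi0:xi1] += amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
        )
    return out


def _render_ridges(shape, segments, amplitude, sigma) -> np.ndarray:
    """Gaussian-cross-section ridges along line segments."""
    rows, cols = shape
    if not segments:
        return np.zeros(shape)
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    dmin = np.full(px.shape[0], np.inf)
    for (x0, y0), (x1, y1) in segments:
        a = np.array([x0, y0])
        b = np.array([x1, y1])
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dist = np.hypot(px[:, 0] - a[0], px[:, 1] - a[1])
        else:
            t = np.clip(((px - a) @ ab) / denom, 0.0, 1.0)
            proj = a[None, :] + t[:, None] * ab[None, :]
            dist = np.hypot(px[:, 0] - proj[:, 0], px[:, 1] - proj[:, 1])
        np.minimum(dmin, dist, out=dmin)
    ridge = amplitude * np.exp(-(dmin**2) / (2 * sigma**2))
    return ridge.reshape(shape)


def _tessellate(centers, island: IslandROI):
    """Voronoi cells of the planted centers, clipped to the island.

    Returns the clipped cell polygons as a :class:`ContourSet` and the list
    of interior shared edges (junction segments) between adjacent cells.
    """
    pts = MultiPoint([Point(p) for p in centers])
    envelope = island.polygon.buffer(island.radius)
    diagram = voronoi_diagram(pts, envelope=envelope)
    # match unordered voronoi cells back to their seed points
    cells = [None] * len(centers)
    for geom in diagram.geoms:
        for i, p in enumerate(centers):
            if cells[i] is None and geom.contains(Point(p)):
                cells[i] = geom
                break
    clipped = []
    for i, cell in enumerate(cells):
        if cell is None:
            raise ValidationError("voronoi cell lookup failed")
        poly = cell.intersection(island.polygon)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        clipped.append(
            CellContour(id=f"cell_{i}", vertices=np.asarray(poly.exterior.coords[:-1]))
        )
    # shared edges between adjacent clipped cells = junction ridges
    segments = []
    tree = cKDTree(centers)
    pairs = sorted(tree.query_pairs(r=4 * _median_nn(centers)))
    for i, j in pairs:
        shared = clipped[i].polygon.intersection(clipped[j].polygon)
        if shared.geom_type == "LineString" and shared.length > 1e-9:
            c0, c1 = shared.coords[0], shared.coords[-1]
            segments.append(((c0[0], c0[1]), (c1[0], c1[1])))
        elif shared.geom_type == "MultiLineString":
            for ls in shared.geoms:
                if ls.length > 1e-9:
                    c0, c1 = ls.coords[0], ls.coords[-1]
                    segments.append(((c0[0], c0[1]), (c1[0], c1[1])))
    return ContourSet(contours=clipped, image_id="synthetic"), segments


def _median_nn(centers) -> float:
    tree = cKDTree(centers)
    d, _ = tree.query(centers, k=2)
    return float(np.median(d[:, 1]))


# ---------------------------------------------------------------------------
# contour-pair fixtures


def generate_contour_pair(
    overlap_fraction: float, shape: str = "square", seed: int = 0
) -> tuple[CellContour, CellContour, float]:
    """Two congruent contours with a prescribed pairwise overlap fraction.

    The second contour is the first translated along x so that
    area(A & B) / area(A) equals ``overlap_fraction`` exactly (shapes whose
    overlap is linear in the shift: axis-aligned squares and 2:1
    rectangles).  For congruent shapes with overlap fraction f the AND/OR
    contact index is f / (2 - f), returned as ``expected_index``.
    """
    f = float(overlap_fraction)
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"overlap_fraction must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    origin = rng.uniform(5.0, 20.0, size=2)
    side = float(rng.uniform(8.0, 15.0))
    if shape == "square":
        w, h = side, side
    elif shape == "rectangle":
        w, h = 2 * side, side
    else:
        raise ParameterError(f"unsupported shape {shape!r}")
    base = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float) + origin
    shift = np.array([w * (1.0 - f) if f > 0 else w + 1.0, 0.0])
    a = CellContour(id="A", vertices=base)
    b = CellContour(id="B", vertices=base + shift)
    expected = f / (2.0 - f) if f > 0 else 0.0
    return a, b, expected
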