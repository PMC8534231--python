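"""Reading and writing of images, contours, tables and configuration.

Coordinate convention used throughout the package: pixel-center coordinates,
origin at the top-left pixel center, ``x`` increases rightward (columns),
``y`` increases downward (rows), 0-based.  Arrays are indexed ``[y, x]``.

Images are single-plane grayscale TIFFs (8- or 16-bit).  Intensities are
held as floating point after load; no background subtraction happens at I/O
time — background handling is an explicit quantification option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .errors import FormatError, SchemaError, ValidationError

_SUPPORTED_DEPTHS = {8: np.uint8, 16: np.uint16}

# TIFF ResolutionUnit tag values -> micrometres per unit
_RES_UNIT_UM = {2: 25400.0, 3: 10000.0}


@dataclass
class MicropatternImage:
    """A single-channel fluorescence image of a micropatterned island.

    Parameters
    ----------
    pixels
        2-D float array of non-negative intensities (arbitrary fluorescence
        units), shape ``(rows, cols)``.
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size
        Physical size of one pixel in micrometres, or ``None`` if unknown.
    channel_label
        Free-text channel name, e.g. ``"TMRM"`` or ``"E-cadherin"``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float | None = None
    channel_label: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"image must be 2-D, got {self.pixels.ndim} dimensions"
            )
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValidationError(
                f"image must be at least 16x16, got {self.pixels.shape}"
            )
        if self.bit_depth not in _SUPPORTED_DEPTHS:
            raise ValidationError(f"unsupported bit depth {self.bit_depth}")
        if np.any(self.pixels < 0):
            raise ValidationError("negative intensities are not allowed")
        if np.any(self.pixels > 2**self.bit_depth - 1):
            raise ValidationError(
                f"intensities exceed {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellContour:
    """A closed, simple polygon tracing one cell, in pixel coordinates.

    Vertices are stored without a duplicated closing vertex and normalized
    to counter-clockwise order (positive signed area in the x-right /
    y-down frame).
    """

    id: str
    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError(
                f"contour '{self.id}': vertices must be an (n, 2) array"
            )
        # drop an explicit closing vertex if present
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValidationError(
                f"contour '{self.id}': needs >= 3 distinct vertices"
            )
        poly = Polygon(v)
        if not poly.is_valid or not poly.is_simple:
            raise ValidationError(
                f"contour '{self.id}': polygon is self-intersecting or invalid"
            )
        if poly.area <= 0:
            raise ValidationError(f"contour '{self.id}': zero-area polygon")
        poly = orient(poly, sign=1.0)  # counter-clockwise
        self.vertices = np.asarray(poly.exterior.coords[:-1], dtype=np.float64)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area in px^2."""
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        return self.polygon.length


@dataclass
class ContourSet:
    """Traced cell outlines belonging to one image."""

    contours: list[CellContour]
    image_id: str | None = None
    units: str = "pixels"

    def __len__(self):
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        """Raise if any vertex falls outside an image of the given shape."""
        rows, cols = shape
        for c in self.contours:
            x, y = c.vertices[:, 0], c.vertices[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > cols - 1 or y.max() > rows - 1:
                raise ValidationError(
                    f"contour '{c.id}' extends outside image bounds {shape}"
                )


def read_image(path) -> MicropatternImage:
    """Read a single-plane grayscale TIFF.

    Bit depth is inferred from the stored dtype; pixel size is taken from
    the TIFF resolution tags when present (inch/cm units), else left unset.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            arr = page.asarray()
            pixel_size = _pixel_size_from_tags(page)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise FormatError(f"cannot read TIFF {path!s}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path!s}: expected single-plane grayscale image, "
            f"got shape {arr.shape} (multi-channel/RGB not supported)"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path!s}: unsupported sample dtype {arr.dtype} (need uint8/uint16)"
        )
    return MicropatternImage(pixels=arr, bit_depth=depth, pixel_size=pixel_size)


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    unit = int(tags["ResolutionUnit"].value)
    if unit not in _RES_UNIT_UM:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    pixels_per_unit = num / den
    return _RES_UNIT_UM[unit] / pixels_per_unit


def write_image(image: MicropatternImage, path) -> None:
    """Write a :class:`MicropatternImage` as an 8- or 16-bit grayscale TIFF.

    Values are rounded to the nearest integer and clipped to the bit-depth
    range; the resolution tag is written (in cm) when ``pixel_size`` is set.
    """
    dtype = _SUPPORTED_DEPTHS[image.bit_depth]
    lim = 2**image.bit_depth - 1
    arr = np.clip(np.rint(image.pixels), 0, lim).astype(dtype)
    kwargs = {}
    if image.pixel_size is not None:
        ppcm = 10000.0 / image.pixel_size  # pixels per centimetre
        kwargs["resolution"] = (ppcm, ppcm)
        kwargs["resolutionunit"] = 3
    tifffile.imwrite(path, arr, **kwargs)


def read_contours(path) -> ContourSet:
    """Read traced cell outlines from JSON.

    Accepts either a bare list ``[{"id": ..., "vertices": [[x, y], ...]}, ...]``
    or an object ``{"image_id": ..., "contours": [...]}``.  Polygons are
    validated (closed, simple, >= 3 vertices) and stored counter-clockwise.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        items, image_id = doc, None
    elif isinstance(doc, dict) and "contours" in doc:
        items, image_id = doc["contours"], doc.get("image_id")
    else:
        raise FormatError(f"{path!s}: not a recognised contour document")
    contours = [
        CellContour(id=str(item.get("id", i)), vertices=item["vertices"])
        for i, item in enumerate(items)
    ]
    return ContourSet(contours=contours, image_id=image_id)


def write_contours(cs: ContourSet, path) -> None:
    doc = {
        "image_id": cs.image_id,
        "units": cs.units,
        "contours": [
            {"id": c.id, "vertices": c.vertices.tolist()} for c in cs.contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def write_table(records, path, schema: list[str] | None = None) -> None:
    """Write keyed rows as CSV, preserving input order.

    All rows must share one key set.  Floats are rendered with 9 significant
    digits so a round-trip read reproduces values to at least 6.  An empty
    record list is only writable when an explicit ``schema`` supplies the
    header.
    """
    records = list(records)
    if not records:
        if schema is None:
            raise SchemaError("empty record list and no explicit schema")
        pd.DataFrame(columns=list(schema)).to_csv(path, index=False)
        return
    keys = list(records[0].keys())
    keyset = set(keys)
    for i, rec in enumerate(records):
        if set(rec.keys()) != keyset:
            raise SchemaError(
                f"row {i} keys {sorted(rec.keys())} != {sorted(keyset)}"
            )
    if schema is not None:
        if set(schema) != keyset:
            raise SchemaError(f"schema {schema} does not match row keys {keys}")
        keys = list(schema)
    df = pd.DataFrame.from_records(records, columns=keys)
    df.to_csv(path, index=False, float_format="%.9g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path) -> dict:
    """Read a YAML (or flat ``key: value``) configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path!s}: config must be a mapping")
    return doc


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)
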