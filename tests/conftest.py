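"""Shared fixtures and oracles for the micropat test suite.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

import numpy as np
import pytest
from skimage.draw import polygon2mask

from micropat import MicropatternImage


def disc_image(
    shape=(512, 512),
    center=(256.0, 256.0),
    radius=100.0,
    inside=200.0,
    outside=0.0,
    bit_depth=16,
):
    """A hard-edged disc: ``inside`` within ``radius`` of center, else ``outside``."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - center[0], yy - center[1])
    pix = np.where(d <= radius, float(inside), float(outside))
    return MicropatternImage(pixels=pix, bit_depth=bit_depth)


def random_convex_polygon(rng, n_max=8, radius=5.0, center=(0.0, 0.0)):
    """Convex hull of random points on a rough circle around ``center``."""
    n = rng.integers(4, n_max + 1)
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(0.5 * radius, radius, n)
    pts = np.column_stack(
        [center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang)]
    )
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return pts[hull.vertices]


def raster_jaccard(va, vb, h=0.01):
    """Brute-force AND/OR index from masks rasterized at ``h`` px resolution.

    Independent of the polygon-clipping implementation: both polygons are
    scan-converted on a grid of pitch ``h`` over their joint bounding box
    and the index is the pixel-count ratio.
    """
    allv = np.vstack([va, vb])
    x0, y0 = allv.min(axis=0) - 2 * h
    x1, y1 = allv.max(axis=0) + 2 * h
    ncol = int(np.ceil((x1 - x0) / h))
    nrow = int(np.ceil((y1 - y0) / h))

    def mask(v):
        rc = np.column_stack([(v[:, 1] - y0) / h, (v[:, 0] - x0) / h])
        return polygon2mask((nrow, ncol), rc)

    ma, mb = mask(va), mask(vb)
    inter = np.count_nonzero(ma & mb)
    union = np.count_nonzero(ma | mb)
    return inter / union if union else 0.0


@pytest.fixture
def clean_disc():
    return disc_image()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
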