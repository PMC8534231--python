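"""Contact index, cell counting, line scans, junction area."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import LineString

import shapely
from micropat import (
    CellContour,
    CellField,
    ContourSet,
    IslandROI,
    MicropatternImage,
    NoiseModel,
    RadialModel,
    SyntheticSpec,
    average_line_scans,
    contact_index,
    count_cells,
    generate,
    junction_area_per_cell,
    line_scan,
)
from micropat.errors import AlignmentError, GeometryError, ParameterError, ValidationError
from micropat.simulate import _render_ridges
from tests.conftest import random_convex_polygon, raster_jaccard


def _square(x0, y0, side, cid="c"):
    return CellContour(
        id=cid,
        vertices=[[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
    )


class TestContactIndex:
    def test_identical_squares(self):
        a, b = _square(0, 0, 10, "a"), _square(0, 0, 10, "b")
        res = contact_index(a, b)
        assert res.index == pytest.approx(1.0, abs=1e-12)
        assert res.and_area == pytest.approx(res.or_area)

    def test_disjoint_squares(self):
        a, b = _square(0, 0, 10, "a"), _square(20, 0, 10, "b")
        res = contact_index(a, b)
        assert res.index == 0.0
        assert res.or_area == pytest.approx(a.area + b.area)

    def test_half_overlapping_unit_squares(self):
        a = _square(0, 0, 1, "a")
        b = CellContour(id="b", vertices=[[0.5, 0], [1.5, 0], [1.5, 1], [0.5, 1]])
        res = contact_index(a, b)
        assert res.and_area == pytest.approx(0.5, abs=1e-12)
        assert res.or_area == pytest.approx(1.5, abs=1e-12)
        assert res.index == pytest.approx(1 / 3, abs=1e-12)

    def test_symmetry_exact(self, rng):
        for _ in range(20):
            va = random_convex_polygon(rng, center=(10, 10))
            vb = random_convex_polygon(rng, center=(12, 11))
            a = CellContour(id="a", vertices=va)
            b = CellContour(id="b", vertices=vb)
            assert contact_index(a, b).index == contact_index(b, a).index

    def test_bounds_and_area_relations(self, rng):
        for _ in range(20):
            a = CellContour(id="a", vertices=random_convex_polygon(rng, center=(10, 10)))
            b = CellContour(id="b", vertices=random_convex_polygon(rng, center=(13, 10)))
            res = contact_index(a, b)
            assert 0.0 <= res.index <= 1.0
            assert res.and_area <= min(a.area, b.area) + 1e-12
            assert res.or_area >= max(a.area, b.area) - 1e-12

    def test_matches_rasterized_brute_force(self, rng):
        # exact clipping vs scan-converted masks at 0.01 px pitch
        for _ in range(30):
            va = random_convex_polygon(rng, center=(10.0, 10.0))
            vb = random_convex_polygon(rng, center=(10.0 + rng.uniform(0, 4), 10.0))
            exact = contact_index(
                CellContour(id="a", vertices=va), CellContour(id="b", vertices=vb)
            ).index
            assert exact == pytest.approx(raster_jaccard(va, vb), abs=0.01)


class TestCountCells:
    def _blob_island(self, seed=5, poisson=True):
        spec = SyntheticSpec(
            seed=seed,
            radial_model=RadialModel("flat", (30.0,)),
            cells=CellField(n=50, min_separation=16.0, blob_sigma=4.0, amplitude=120.0),
            noise=NoiseModel(poisson=poisson),
            background=5.0,
        )
        return generate(spec)

    def test_recovers_planted_blobs_noise_free(self):
        img, gt = self._blob_island(poisson=False)
        res = count_cells(img, gt.island, cell_diameter=16)
        assert res.count == 50
        d, _ = cKDTree(gt.cell_centers).query(res.positions)
        assert d.max() < 2.0

    def test_recall_and_false_positives_under_shot_noise(self):
        img, gt = self._blob_island(poisson=True)
        res = count_cells(img, gt.island, cell_diameter=16)
        d, idx = cKDTree(gt.cell_centers).query(res.positions)
        true_pos = len(set(idx[d <= 8.0]))
        assert true_pos / 50 >= 0.95
        assert (res.count - true_pos) / max(res.count, 1) <= 0.05

    def test_flat_roi_counts_zero(self):
        img = MicropatternImage(np.full((128, 128), 40.0), bit_depth=16)
        roi = IslandROI(centroid=(64, 64), boundary_kind="circle", radius=50)
        assert count_cells(img, roi, cell_diameter=10).count == 0

    def test_count_invariant_to_intensity_scaling(self):
        img, gt = self._blob_island(poisson=False)
        doubled = MicropatternImage(img.pixels * 2, bit_depth=16)
        a = count_cells(img, gt.island, cell_diameter=16)
        b = count_cells(doubled, gt.island, cell_diameter=16)
        assert a.count == b.count
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_density_units_follow_pixel_size(self):
        img, gt = self._blob_island(poisson=False)
        res = count_cells(img, gt.island, cell_diameter=16)
        assert res.density_units == "cells/px^2"
        sized = MicropatternImage(img.pixels, bit_depth=16, pixel_size=1.0)
        res2 = count_cells(sized, gt.island, cell_diameter=16)
        assert res2.density_units == "cells/mm^2"
        assert res2.density == pytest.approx(res.density * 1e6)

    def test_parameter_errors(self):
        img = MicropatternImage(np.full((64, 64), 40.0), bit_depth=16)
        roi = IslandROI(centroid=(32, 32), boundary_kind="circle", radius=20)
        with pytest.raises(ParameterError):
            count_cells(img, roi, cell_diameter=2)
        with pytest.raises(ParameterError):
            count_cells(img, roi, cell_diameter=60)


class TestLineScan:
    def _ridge_image(self, amplitude=200.0, baseline=50.0, sigma=2.0, x=64.0):
        pix = np.full((128, 128), baseline)
        pix += _render_ridges((128, 128), [((x, 0.0), (x, 127.0))], amplitude, sigma)
        return MicropatternImage(pix, bit_depth=16)

    def test_constant_image_flat_profile(self):
        img = MicropatternImage(np.full((64, 64), 77.0), bit_depth=16)
        scan = line_scan(img, (10, 32), (50, 32), width=3, n_samples=21)
        np.testing.assert_allclose(scan.intensity, 77.0)
        assert scan.positions[0] == pytest.approx(-20.0)
        assert scan.positions[-1] == pytest.approx(20.0)

    def test_gaussian_ridge_peak_at_junction(self):
        img = self._ridge_image()
        scan = line_scan(img, (54, 64), (74, 64), width=1, n_samples=41)
        peak_i = int(np.argmax(scan.intensity))
        spacing = scan.positions[1] - scan.positions[0]
        assert abs(scan.positions[peak_i]) <= spacing  # within 1 sample of 0
        assert scan.intensity[peak_i] == pytest.approx(250.0, rel=0.05)

    def test_reversed_segment_mirrors_profile(self):
        img = self._ridge_image(x=60.0)
        fwd = line_scan(img, (50, 64), (70, 64), width=1, n_samples=41)
        rev = line_scan(img, (70, 64), (50, 64), width=1, n_samples=41)
        np.testing.assert_allclose(rev.intensity, fwd.intensity[::-1], atol=1e-9)

    def test_additive_constant_shifts_profile(self):
        img = self._ridge_image()
        shifted = MicropatternImage(img.pixels + 100.0, bit_depth=16)
        a = line_scan(img, (54, 64), (74, 64), n_samples=21)
        b = line_scan(shifted, (54, 64), (74, 64), n_samples=21)
        np.testing.assert_allclose(b.intensity - a.intensity, 100.0, atol=1e-9)

    def test_out_of_bounds_rejected(self):
        img = MicropatternImage(np.zeros((64, 64)), bit_depth=16)
        with pytest.raises(GeometryError):
            line_scan(img, (-5, 32), (50, 32))
        with pytest.raises(GeometryError):
            line_scan(img, (10, 0), (50, 0), width=5)  # width pushes off-image


class TestAverageLineScans:
    def test_identical_profiles(self):
        img = MicropatternImage(np.full((64, 64), 10.0), bit_depth=16)
        scans = [line_scan(img, (10, 32), (50, 32), n_samples=11) for _ in range(18)]
        prof = average_line_scans(scans)
        assert prof.n_scans == 18
        np.testing.assert_allclose(prof.mean_intensity, 10.0)
        np.testing.assert_allclose(prof.sd_intensity, 0.0)

    def test_mirror_pair_averages_symmetric(self):
        pix = np.tile(np.linspace(0, 100, 64), (64, 1))
        img = MicropatternImage(pix, bit_depth=16)
        fwd = line_scan(img, (10, 32), (50, 32), n_samples=21)
        rev = line_scan(img, (50, 32), (10, 32), n_samples=21)
        prof = average_line_scans([fwd, rev])
        np.testing.assert_allclose(prof.mean_intensity, prof.mean_intensity[::-1], atol=1e-9)

    def test_jittered_amplitudes_recover_mean(self, rng):
        amps = 200.0 * rng.uniform(0.9, 1.1, 20)
        scans = []
        for a in amps:
            pix = np.full((128, 128), 50.0)
            pix += _render_ridges((128, 128), [((64.0, 0.0), (64.0, 127.0))], a, 2.0)
            img = MicropatternImage(pix, bit_depth=16)
            scans.append(line_scan(img, (54, 64), (74, 64), width=1, n_samples=41))
        prof = average_line_scans(scans)
        peak = prof.mean_intensity.max() - 50.0
        assert peak == pytest.approx(amps.mean(), rel=0.02)

    def test_mismatched_sampling_rejected(self):
        img = MicropatternImage(np.zeros((64, 64)), bit_depth=16)
        a = line_scan(img, (10, 32), (50, 32), n_samples=11)
        b = line_scan(img, (10, 32), (50, 32), n_samples=21)
        with pytest.raises(AlignmentError):
            average_line_scans([a, b])


class TestJunctionArea:
    def test_zero_image_all_zero_areas(self):
        img = MicropatternImage(np.zeros((64, 64)), bit_depth=16)
        cs = ContourSet(contours=[_square(10, 10, 20, "a"), _square(35, 10, 20, "b")])
        with pytest.warns(UserWarning):
            df = junction_area_per_cell(img, cs)
        assert (df["junction_area"] == 0).all()

    def test_painted_boundary_matches_perimeter_times_width(self):
        # a 40x40 square cell on half-integer coordinates whose boundary
        # carries a 2-px-wide bright band (pixel centers at distance 0.5
        # on both sides of each boundary line)
        cell = _square(30.5, 30.5, 40, "a")
        ring = LineString(np.vstack([cell.vertices, cell.vertices[:1]])).buffer(1.0)
        yy, xx = np.mgrid[0:128, 0:128]
        painted = shapely.contains_xy(ring, xx.ravel(), yy.ravel()).reshape(128, 128)
        img = MicropatternImage(np.where(painted, 200.0, 0.0), bit_depth=16)
        df = junction_area_per_cell(
            img,
            ContourSet(contours=[cell]),
            threshold_mode="fixed",
            threshold=100.0,
            band_halfwidth=2.0,
        )
        expected = cell.perimeter * 2.0
        assert df["junction_area"].iloc[0] == pytest.approx(expected, rel=0.10)

    def test_otsu_invariant_to_intensity_doubling(self):
        rng = np.random.default_rng(3)
        pix = np.where(rng.uniform(size=(64, 64)) < 0.3, 200.0, 20.0)
        cs = ContourSet(contours=[_square(5, 5, 30, "a"), _square(25, 25, 30, "b")])
        img = MicropatternImage(pix, bit_depth=16)
        doubled = MicropatternImage(pix * 2, bit_depth=16)
        a = junction_area_per_cell(img, cs)
        b = junction_area_per_cell(doubled, cs)
        np.testing.assert_array_equal(a["junction_area"], b["junction_area"])

    def test_micron_units_with_pixel_size(self):
        cell = _square(10, 10, 20, "a")
        pix = np.full((64, 64), 0.0)
        pix[10, 10:30] = 200.0
        img = MicropatternImage(pix, bit_depth=16, pixel_size=0.5)
        df = junction_area_per_cell(
            img, ContourSet(contours=[cell]), threshold_mode="fixed", threshold=100.0
        )
        assert df["area_units"].iloc[0] == "um^2"


def test_zero_area_contour_rejected_at_construction():
    with pytest.raises(ValidationError):
        CellContour(id="flat", vertices=[[0, 0], [5, 0], [10, 0]])
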