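"""Image/contour I/O, rasterization, boundary tracing and the radial form."""

import json

import numpy as np
import pytest
from PIL import Image

import echofeat as ef
from echofeat.roi_io import boundary_pixel_set, chain_perimeter

from conftest import make_disc_roi, random_phantom_spec


class TestLoadImage:
    def test_constant_grey_png_roundtrip(self, tmp_path):
        arr = np.full((64, 64), 128, dtype=np.uint8)
        p = tmp_path / "c.png"
        Image.fromarray(arr, mode="L").save(p)
        img = ef.load_image(p)
        assert img.pixels.dtype == np.uint8
        assert np.all(img.pixels == 128)

    def test_equal_channel_rgb_collapses_to_grey(self, tmp_path):
        rgb = np.full((16, 16, 3), 50, dtype=np.uint8)
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb, mode="RGB").save(p)
        assert np.all(ef.load_image(p).pixels == 50)

    def test_phantom_write_read_is_pixel_identical(self, tmp_path):
        img, _, _ = ef.make_phantom(ef.PhantomSpec(seed=11))
        p = tmp_path / "ph.png"
        ef.roi_io.save_image(img, p)
        assert np.array_equal(ef.load_image(p).pixels, img.pixels)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ef.load_image(tmp_path / "absent.png")

    def test_too_small_image_rejected(self, tmp_path):
        p = tmp_path / "tiny.png"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8), mode="L").save(p)
        with pytest.raises(ef.ValidationError):
            ef.load_image(p)


class TestRasterizeContour:
    def test_integer_corner_square_is_inclusive(self):
        c = ef.Contour([[10, 10], [10, 25], [10, 40], [25, 40],
                        [40, 40], [40, 25], [40, 10], [25, 10]])
        # collinear midpoints pad the square to the 8-vertex minimum
        mask = ef.rasterize_contour(c, (64, 64))
        assert mask.sum() == 31 * 31

    def test_circle_area_close_to_continuous(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        c = ef.Contour(np.stack([40 + 30 * np.sin(th), 40 + 30 * np.cos(th)], 1))
        mask = ef.rasterize_contour(c, (80, 80))
        assert abs(mask.sum() - np.pi * 30**2) / (np.pi * 30**2) < 0.02

    def test_matches_point_in_polygon_oracle_on_circle(self):
        # brute-force scan: pixel centers covered by the polygon (shapely)
        from shapely.geometry import Point, Polygon

        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        verts = np.stack([40 + 30 * np.sin(th), 40 + 30 * np.cos(th)], 1)
        mask = ef.rasterize_contour(ef.Contour(verts), (80, 80))
        poly = Polygon([(c, r) for r, c in verts])
        oracle = sum(poly.covers(Point(c, r))
                     for r in range(80) for c in range(80))
        assert abs(int(mask.sum()) - oracle) <= 0.01 * oracle + 5

    def test_vertices_outside_shape_rejected(self):
        c = ef.Contour([[10, 10], [10, 25], [10, 40], [25, 40],
                        [40, 40], [40, 70], [40, 10], [25, 10]])
        with pytest.raises(ef.ValidationError):
            ef.rasterize_contour(c, (64, 64))

    def test_degenerate_contours_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.Contour([[0, 0], [1, 1], [2, 2]])  # < 8 vertices
        collinear = [[i, i] for i in range(10)]
        with pytest.raises(ef.ValidationError):
            ef.rasterize_contour(ef.Contour(collinear), (20, 20))  # zero area


class TestTraceBoundary:
    def test_square_boundary_count(self, square_roi):
        assert len(square_roi.boundary) == 4 * 31 - 4

    def test_thin_mask_rejected(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 5:9] = True  # 1x4 line traces to 6 < 8 pixels
        with pytest.raises(ef.ValidationError):
            ef.trace_boundary(mask)

    def test_empty_and_split_masks_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.trace_boundary(np.zeros((16, 16), dtype=bool))
        two = np.zeros((32, 32), dtype=bool)
        two[2:8, 2:8] = True
        two[20:26, 20:26] = True
        with pytest.raises(ef.ValidationError):
            ef.trace_boundary(two)

    def test_traced_set_equals_brute_force_boundary(self):
        """Traced pixels == foreground pixels with a 4-adjacent background
        neighbour, for 100 random phantoms."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            spec = random_phantom_spec(rng)
            _, contour, _ = ef.make_phantom(spec)
            mask = ef.rasterize_contour(contour, spec.canvas)
            traced = ef.trace_boundary(mask)
            tset = set(map(tuple, traced.vertices.astype(int)))
            bset = set(map(tuple, np.argwhere(boundary_pixel_set(mask))))
            assert tset == bset

    def test_traced_order_is_clockwise_and_8_adjacent(self, disc_roi):
        v = disc_roi.boundary.vertices
        steps = np.abs(np.diff(v, axis=0, append=v[:1]))
        assert np.all(steps.max(axis=1) == 1)
        x, y = v[:, 1], v[:, 0]
        assert np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) > 0

    def test_rasterize_trace_roundtrip_reaches_fixed_point(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec = random_phantom_spec(rng)
            _, contour, _ = ef.make_phantom(spec)
            m1 = ef.rasterize_contour(contour, spec.canvas)
            m2 = ef.rasterize_contour(ef.trace_boundary(m1), spec.canvas)
            m3 = ef.rasterize_contour(ef.trace_boundary(m2), spec.canvas)
            assert np.array_equal(m2, m3)


class TestCentroid:
    def test_square_centroid_by_symmetry(self, square_roi):
        assert square_roi.centroid == (25.0, 25.0)

    def test_two_pixel_mean(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = mask[0, 2] = True
        assert ef.centroid(mask) == (0.0, 1.0)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(3)
        spec = random_phantom_spec(rng)
        _, contour, _ = ef.make_phantom(spec)
        mask = ef.rasterize_contour(contour, spec.canvas)
        expect = tuple(np.argwhere(mask).mean(axis=0))
        assert ef.centroid(mask) == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.centroid(np.zeros((8, 8), dtype=bool))


class TestRadialSequence:
    def test_disc_radii_near_radius(self, disc_roi):
        seq = ef.to_radial_sequence(disc_roi.boundary, disc_roi.centroid)
        assert len(seq) == len(disc_roi.boundary)
        assert np.all(seq.r > 48.5) and np.all(seq.r < 50.8)

    def test_square_corner_to_edge_ratio(self, square_roi):
        seq = ef.to_radial_sequence(square_roi.boundary, square_roi.centroid)
        assert seq.r.max() / seq.r.min() == pytest.approx(np.sqrt(2), rel=0.03)

    def test_translation_leaves_radii_unchanged(self):
        roi = make_disc_roi(30, canvas=(120, 120))
        mask2 = np.roll(np.roll(roi.mask, 5, axis=0), 7, axis=1)
        roi2 = ef.build_roi(roi.image.pixels, mask2)
        s1 = ef.to_radial_sequence(roi.boundary, roi.centroid)
        s2 = ef.to_radial_sequence(roi2.boundary, roi2.centroid)
        assert sorted(s1.r.round(9)) == pytest.approx(sorted(s2.r.round(9)))

    def test_centroid_on_boundary_rejected(self):
        v = [[0, i] for i in range(8)]
        with pytest.raises(ef.ValidationError):
            ef.to_radial_sequence(ef.Contour(v), (0.0, 3.0))

    def test_angles_in_range_and_validated(self, disc_roi):
        seq = ef.to_radial_sequence(disc_roi.boundary, disc_roi.centroid)
        assert np.all(seq.theta >= 0) and np.all(seq.theta < 2 * np.pi)
        with pytest.raises(ef.ValidationError):
            ef.RadialSequence(np.ones(10), np.full(10, 7.0))


class TestContourFiles:
    def test_json_contour_roundtrip(self, tmp_path):
        verts = [[10, 10], [10, 40], [40, 40], [40, 10],
                 [10, 25], [25, 40], [40, 25], [25, 10]]
        p = tmp_path / "c.json"
        p.write_text(json.dumps({"vertices": verts}))
        loaded = ef.load_contour(p)
        assert isinstance(loaded, ef.Contour)
        assert np.array_equal(loaded.vertices, np.asarray(verts, dtype=float))

    def test_mask_png_contour(self, tmp_path):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:25, 8:25] = 255
        p = tmp_path / "m.png"
        Image.fromarray(mask, mode="L").save(p)
        loaded = ef.load_contour(p)
        assert loaded.dtype == bool and loaded.sum() == 17 * 17


def test_geometry_is_translation_invariant():
    """C, S and the radius multiset are unchanged by embedding offset."""
    roi = make_disc_roi(30, canvas=(150, 150))
    mask2 = np.roll(np.roll(roi.mask, 11, axis=0), -9, axis=1)
    roi2 = ef.build_roi(roi.image.pixels, mask2)
    assert len(roi.boundary) == len(roi2.boundary)
    assert roi.area_px == roi2.area_px
    assert chain_perimeter(roi.boundary) == pytest.approx(
        chain_perimeter(roi2.boundary))


def test_boundary_pixels_are_foreground_with_background_8_neighbour(disc_roi):
    """LesionROI invariant: every traced pixel touches background."""
    mask = disc_roi.mask
    padded = np.pad(mask, 1)
    for r, c in disc_roi.boundary.vertices.astype(int):
        assert mask[r, c]
        assert not padded[r:r + 3, c:c + 3].all()
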