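"""Axis placement, boundary extraction, half splitting, resampling."""

import numpy as np
import pytest

from lensmorph import (
    AxisFrame,
    Calibration,
    DegenerateMaskError,
    HalfProfile,
    LensMask,
    PhantomSpec,
    extract_edges,
    find_axes,
    lens_volume,
    render_phantom,
    resample_profile,
    split_halves,
)


def make_ellipse(a_rows=30, b_cols=50, pad=5, offset=(0, 0), ppm=100.0):
    n_r = 2 * (a_rows + pad) + 1 + abs(offset[0])
    n_c = 2 * (b_cols + pad) + 1 + abs(offset[1])
    c_r = a_rows + pad + max(offset[0], 0)
    c_c = b_cols + pad + max(offset[1], 0)
    rr, cc = np.indices((n_r, n_c))
    m = ((rr - c_r) / a_rows) ** 2 + ((cc - c_c) / b_cols) ** 2 <= 1.0
    return LensMask(m, Calibration(ppm)), (c_r, c_c)


def brute_force_boundary(m):
    """Oracle: foreground pixels with any 8-neighbour background or border."""
    out = set()
    R, C = m.shape
    for r in range(R):
        for c in range(C):
            if not m[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < R and 0 <= cc < C) or not m[rr, cc]:
                        out.add((r, c))
    return out


class TestFindAxes:
    def test_centered_ellipse_axes_at_centroid(self):
        mask, (c_r, c_c) = make_ellipse()
        frame, _ = find_axes(mask, mode="vertical")
        assert frame.axis_column == pytest.approx(c_c, abs=1e-9)
        assert frame.equator_row == pytest.approx(c_r, abs=0.5)

    def test_translation_equivariance(self):
        mask0, (r0, c0) = make_ellipse()
        mask1, (r1, c1) = make_ellipse(offset=(7, 11))
        f0, _ = find_axes(mask0)
        f1, _ = find_axes(mask1)
        assert f1.axis_column - f0.axis_column == pytest.approx(c1 - c0, abs=1e-9)
        assert f1.equator_row - f0.equator_row == pytest.approx(r1 - r0, abs=1e-9)

    def test_asymmetric_phantom_equator_at_half_ellipse_junction(self):
        spec = PhantomSpec("asymmetric", 0.5, 1.0, 1.2, pixels_per_mm=100)
        mask, truth = render_phantom(spec)
        # oracle: per-row foreground run-length argmax
        widths = mask.mask.sum(axis=1)
        expect = float(np.flatnonzero(widths == widths.max()).mean())
        frame, _ = find_axes(mask)
        assert frame.equator_row == pytest.approx(expect, abs=1e-9)
        assert frame.equator_row == pytest.approx(truth.equator_row, abs=1.0)

    def test_thin_mask_degenerate(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 9:11] = True  # 2 px wide
        with pytest.raises(DegenerateMaskError):
            find_axes(LensMask(m, Calibration(10.0)))

    def test_auto_mode_recovers_rotated_measures(self):
        from scipy import ndimage

        mask, truth = render_phantom(PhantomSpec.spheroid(0.8, 1.2, pixels_per_mm=80))
        frame, m2 = find_axes(mask)
        upright = lens_volume(m2, frame)
        rot = ndimage.rotate(mask.mask.astype(np.uint8), 35, reshape=True, order=0)
        from lensmorph import clean_mask

        tilted = clean_mask(LensMask(rot.astype(bool), mask.calibration))
        frame2, m3 = find_axes(tilted, mode="auto")
        recovered = lens_volume(m3, frame2)
        assert recovered.volume_mm3 == pytest.approx(upright.volume_mm3, rel=0.01)
        assert recovered.equatorial_diameter_mm == pytest.approx(
            upright.equatorial_diameter_mm, abs=2 / 80.0
        )


class TestExtractEdges:
    def test_single_pixel_is_its_own_edge(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        edges = extract_edges(LensMask(m, Calibration(10.0)))
        assert edges.tolist() == [[2, 2]]

    def test_rectangle_perimeter_count(self):
        w, h = 13, 7
        m = np.zeros((h + 4, w + 4), dtype=bool)
        m[2 : 2 + h, 2 : 2 + w] = True
        edges = extract_edges(LensMask(m, Calibration(10.0)))
        assert len(edges) == 2 * w + 2 * h - 4

    def test_disk_edges_near_ideal_circle(self, disk_factory):
        r = 200
        mask = disk_factory(r)
        c = mask.mask.shape[0] // 2
        edges = extract_edges(mask)
        dist = np.hypot(edges[:, 0] - c, edges[:, 1] - c)
        assert np.all(np.abs(dist - r) <= 1.5)

    def test_matches_brute_force_boundary_oracle(self, disk_factory):
        mask = disk_factory(9)
        edges = {tuple(e) for e in extract_edges(mask)}
        assert edges == brute_force_boundary(mask.mask)

    def test_matches_skimage_boundary(self, disk_factory):
        from skimage.segmentation import find_boundaries

        mask = disk_factory(15)
        edges = np.zeros_like(mask.mask)
        idx = extract_edges(mask)
        edges[idx[:, 0], idx[:, 1]] = True
        ref = find_boundaries(mask.mask, connectivity=2, mode="inner")
        assert np.array_equal(edges, ref)


class TestSplitHalves:
    def test_symmetric_disk_halves_balanced_and_mirrored(self, disk_factory):
        mask = disk_factory(20)
        frame, _ = find_axes(mask)
        edges = extract_edges(mask)
        left, right = split_halves(edges, frame, mask.calibration)
        assert abs(left.n - right.n) <= 1
        assert sorted(left.y.tolist()) == pytest.approx(sorted(right.y.tolist()))

    def test_unit_conversion(self):
        cal = Calibration(100.0)
        frame = AxisFrame(axis_column=0.0, equator_row=0.0)
        edges = np.array([[0, 250], [1, 250]])
        _, right = split_halves(edges, frame, cal)
        assert right.y[0] == pytest.approx(2.5)
        assert right.x[1] == pytest.approx(0.01)

    def test_mirror_flip_swaps_halves(self, disk_factory):
        mask = disk_factory(17)
        frame, _ = find_axes(mask)
        edges = extract_edges(mask)
        l0, r0 = split_halves(edges, frame, mask.calibration)
        flipped = LensMask(mask.mask[:, ::-1], mask.calibration)
        frame2, _ = find_axes(flipped)
        l1, r1 = split_halves(extract_edges(flipped), frame2, mask.calibration)
        assert sorted(zip(l0.x, l0.y)) == pytest.approx(sorted(zip(r1.x, r1.y)))
        assert sorted(zip(r0.x, r0.y)) == pytest.approx(sorted(zip(l1.x, l1.y)))

    def test_scale_equivariance(self, disk_factory):
        mask = disk_factory(15, ppm=100.0)
        frame, _ = find_axes(mask)
        edges = extract_edges(mask)
        _, r100 = split_halves(edges, frame, Calibration(100.0))
        _, r200 = split_halves(edges, frame, Calibration(200.0))
        assert r200.x == pytest.approx(r100.x / 2)
        assert r200.y == pytest.approx(r100.y / 2)

    def test_asymmetric_phantom_max_y_equals_equatorial_semi_axis(self):
        mask, truth = render_phantom(
            PhantomSpec("asymmetric", 0.5, 1.0, 1.2, pixels_per_mm=100)
        )
        frame, _ = find_axes(mask)
        left, right = split_halves(extract_edges(mask), frame, mask.calibration)
        for half in (left, right):
            assert half.y.max() == pytest.approx(1.2, abs=0.01)


class TestResampleProfile:
    def test_outermost_pixel_wins(self):
        half = HalfProfile(x=[0.0, 0.0, 1.0], y=[3.0, 5.0, 4.0], side="right")
        out = resample_profile(half)
        assert out.x.tolist() == [0.0, 1.0]
        assert out.y.tolist() == [5.0, 4.0]

    def test_idempotent(self):
        half = HalfProfile(
            x=[0.0, 0.0, 1.0, 2.0], y=[3.0, 5.0, 4.0, 1.0], side="left",
            px_size_mm=0.01,
        )
        once = resample_profile(half)
        twice = resample_profile(once)
        assert np.array_equal(once.x, twice.x)
        assert np.array_equal(once.y, twice.y)

    def test_disk_half_matches_analytic_circle(self, disk_factory):
        r_px, ppm = 100, 100.0
        mask = disk_factory(r_px, ppm=ppm)
        frame, _ = find_axes(mask)
        _, right = split_halves(extract_edges(mask), frame, mask.calibration)
        out = resample_profile(right)
        sel = np.abs(out.x) < 0.9  # avoid the vertical-tangent poles
        pred = np.sqrt((r_px / ppm) ** 2 - out.x[sel] ** 2)
        assert np.all(np.abs(out.y[sel] - pred) <= 1.0 / ppm)

    def test_strictly_increasing_x(self, disk_factory):
        mask = disk_factory(30)
        frame, _ = find_axes(mask)
        left, right = split_halves(extract_edges(mask), frame, mask.calibration)
        for half in (left, right):
            out = resample_profile(half)
            assert np.all(np.diff(out.x) > 0)
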