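"""Segmentation stage: interior erasure, geodesic distance, boundary
extraction, Fourier smoothing, ellipse fitting, view classification."""

import heapq

import numpy as np
import pytest

from nmfpick import (
    BoundaryCurve,
    CandidateRejected,
    EllipseFitError,
    InvalidInputError,
    RegionCandidate,
    classify_view,
    erase_interior,
    extract_boundary,
    fit_ellipse,
    fourier_smooth,
    geodesic_map,
)
from nmfpick.segmentation import SegmentationConfig


def dijkstra_chamfer(border, source):
    """Independent 8-neighbor shortest-path oracle (steps 1 / sqrt(2))."""
    m, n = border.shape
    dist = np.full((m, n), np.inf)
    if border[source]:
        return dist
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, (i, j) = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < m and 0 <= nj < n and not border[ni, nj]:
                    step = np.sqrt(2.0) if di and dj else 1.0
                    if d + step < dist[ni, nj]:
                        dist[ni, nj] = d + step
                        heapq.heappush(heap, (d + step, (ni, nj)))
    return dist


def ellipse_points(cx, cy, a, b, theta, n=32):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = cx + a * np.cos(t) * np.cos(theta) - b * np.sin(t) * np.sin(theta)
    y = cy + a * np.cos(t) * np.sin(theta) + b * np.sin(t) * np.cos(theta)
    return np.column_stack([y, x])  # (row, col)


class TestEraseInterior:
    def test_filled_disk_leaves_ring_without_interior(self):
        rr, cc = np.mgrid[0:21, 0:21]
        disk = np.hypot(rr - 10, cc - 10) <= 8
        border = erase_interior(disk)
        # oracle: pixels whose full 8-neighborhood is foreground are interior
        interior = np.zeros_like(disk)
        for i in range(1, 20):
            for j in range(1, 20):
                interior[i, j] = disk[i - 1 : i + 2, j - 1 : j + 2].all()
        np.testing.assert_array_equal(border, disk & ~interior)
        assert not (border & interior).any()

    def test_thin_ring_unchanged(self):
        rr, cc = np.mgrid[0:31, 0:31]
        dist = np.hypot(rr - 15, cc - 15)
        ring = np.abs(dist - 10) < 0.6  # 1 px wide
        np.testing.assert_array_equal(erase_interior(ring), ring)

    def test_empty_mask(self):
        empty = np.zeros((8, 8), dtype=bool)
        np.testing.assert_array_equal(erase_interior(empty), empty)


class TestGeodesicMap:
    def test_open_grid_corner_distance(self):
        g = geodesic_map(np.zeros((11, 11), dtype=bool), (5, 5))
        assert g.distances[0, 0] == pytest.approx(5 * np.sqrt(2))
        assert g.distances[5, 5] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        border = rng.random((24, 32)) < 0.25
        border[12, 16] = False
        g = geodesic_map(border, (12, 16))
        oracle = dijkstra_chamfer(border, (12, 16))
        np.testing.assert_allclose(g.distances, oracle, atol=1e-9)

    def test_closed_ring_encloses_source(self):
        rr, cc = np.mgrid[0:41, 0:41]
        dist = np.hypot(rr - 20, cc - 20)
        ring = np.abs(dist - 12) <= 1
        g = geodesic_map(ring, (20, 20))
        assert np.isinf(g.distances[dist > 14]).all()
        assert np.isfinite(g.distances[dist < 10]).all()

    def test_open_border_leaks_through_gap_only(self):
        rr, cc = np.mgrid[0:41, 0:41]
        dist = np.hypot(rr - 20, cc - 20)
        angle = np.arctan2(rr - 20, cc - 20)
        ring = (np.abs(dist - 12) <= 1) & ~(np.abs(angle) < 0.35)  # gap at 0 rad
        g = geodesic_map(ring, (20, 20))
        outside = (20, 2)  # opposite the gap: must route around the ring
        assert np.isfinite(g.distances[outside])
        assert g.distances[outside] > np.hypot(0, 18)
        oracle = dijkstra_chamfer(ring, (20, 20))
        np.testing.assert_allclose(g.distances, oracle, atol=1e-9)

    def test_source_on_border_rejected(self):
        border = np.zeros((9, 9), dtype=bool)
        border[4, 4] = True
        with pytest.raises(InvalidInputError):
            geodesic_map(border, (4, 4))


def _candidate_with_distances(d):
    return RegionCandidate(
        label=1,
        centroid=(20.0, 20.0),
        area=400,
        bbox=(0, 0, 41, 41),
        border_distances=np.asarray(d),
    )


class TestExtractBoundary:
    def test_ring_phantom_recovers_circle(self):
        rr, cc = np.mgrid[0:61, 0:61]
        dist = np.hypot(rr - 30, cc - 30)
        ring = np.abs(dist - 20) <= 1
        g = geodesic_map(ring, (30, 30))
        cand = RegionCandidate(
            label=1, centroid=(30.0, 30.0), area=100, bbox=(0, 0, 61, 61),
            border_distances=np.full(64, 20),
        )
        boundary = extract_boundary(g, cand)
        radii = np.hypot(
            boundary.points[:, 0] - 30, boundary.points[:, 1] - 30
        )
        assert boundary.is_closed
        assert np.abs(radii - 20).mean() < 1.5

    def test_no_border_evidence_rejected(self):
        g = geodesic_map(np.zeros((41, 41), dtype=bool), (20, 20))
        with pytest.raises(CandidateRejected):
            extract_boundary(g, _candidate_with_distances(np.zeros(64, dtype=int)))

    def test_convex_blob_contour_is_closed_and_simple(self):
        rr, cc = np.mgrid[0:41, 0:41]
        blob = np.hypot(rr - 20, cc - 18) <= 9
        border = erase_interior(blob)
        g = geodesic_map(border, (20, 18))
        boundary = extract_boundary(g, _candidate_with_distances(np.full(64, 9)))
        assert boundary.is_closed
        pts = boundary.points
        # simple: no two distinct vertices coincide
        _, counts = np.unique(np.round(pts, 6), axis=0, return_counts=True)
        assert counts.max() == 1


class TestFourierSmooth:
    def test_exact_circle_unchanged(self):
        pts = ellipse_points(30, 30, 10, 10, 0.0, n=64)
        out = fourier_smooth(BoundaryCurve(points=pts), 0.98)
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_jitter_is_attenuated(self, rng):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        r = 20 + 1.0 * np.sin(25 * t)
        pts = np.column_stack([40 + r * np.sin(t), 40 + r * np.cos(t)])
        out = fourier_smooth(BoundaryCurve(points=pts), 0.98)
        dev_in = np.abs(np.hypot(pts[:, 0] - 40, pts[:, 1] - 40) - 20).max()
        dev_out = np.abs(
            np.hypot(out.points[:, 0] - 40, out.points[:, 1] - 40) - 20
        ).max()
        assert dev_out < dev_in

    def test_energy_retention_contract(self, rng):
        pts = ellipse_points(50, 50, 18, 9, 0.4, n=64)
        pts += rng.normal(0, 0.6, pts.shape)
        out = fourier_smooth(BoundaryCurve(points=pts), 0.98)
        z_in = pts[:, 1] + 1j * pts[:, 0]
        z_out = out.points[:, 1] + 1j * out.points[:, 0]
        e_in = np.abs(np.fft.fft(z_in - z_in.mean())) ** 2
        e_out = np.abs(np.fft.fft(z_out - z_out.mean())) ** 2
        assert e_out.sum() / e_in.sum() >= 0.98

    def test_idempotent(self, rng):
        pts = ellipse_points(50, 50, 18, 9, 0.4, n=64) + rng.normal(0, 0.5, (64, 2))
        once = fourier_smooth(BoundaryCurve(points=pts), 0.98)
        twice = fourier_smooth(once, 0.98)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-9)

    def test_open_curve_rejected(self):
        pts = ellipse_points(30, 30, 10, 10, 0.0)
        with pytest.raises(InvalidInputError):
            fourier_smooth(BoundaryCurve(points=pts, is_closed=False))


class TestFitEllipse:
    def test_exact_recovery(self):
        pts = ellipse_points(40, 60, 15, 9, np.pi / 6)
        e = fit_ellipse(pts)
        assert e.cx == pytest.approx(40, abs=1e-6)
        assert e.cy == pytest.approx(60, abs=1e-6)
        assert e.a == pytest.approx(15, abs=1e-6)
        assert e.b == pytest.approx(9, abs=1e-6)
        assert e.theta == pytest.approx(np.pi / 6, abs=1e-6)

    def test_circle_angle_convention(self):
        pts = ellipse_points(25, 25, 12, 12, 0.7)
        e = fit_ellipse(pts)
        assert e.a == pytest.approx(e.b, abs=1e-6)
        assert e.theta == 0.0

    def test_outliers_rejected_by_median_pass(self):
        pts = ellipse_points(40, 60, 15, 9, np.pi / 6)
        outliers = np.array([[95.0, 10.0], [5.0, 95.0], [90.0, 90.0]])
        e = fit_ellipse(np.vstack([pts, outliers]))
        assert np.hypot(e.cx - 40, e.cy - 60) < 0.5

    def test_translation_equivariance(self):
        pts = ellipse_points(40, 60, 15, 9, 0.3)
        e0 = fit_ellipse(pts)
        e1 = fit_ellipse(pts + np.array([3.25, -7.5]))  # (drow, dcol)
        assert e1.cx - e0.cx == pytest.approx(-7.5, abs=1e-6)
        assert e1.cy - e0.cy == pytest.approx(3.25, abs=1e-6)

    def test_rotation_equivariance(self):
        phi = 0.41
        pts = ellipse_points(0, 0, 15, 9, 0.3)
        rot = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        xy = pts[:, ::-1] @ rot.T
        e0 = fit_ellipse(pts)
        e1 = fit_ellipse(xy[:, ::-1])
        dtheta = (e1.theta - e0.theta) % np.pi
        assert min(dtheta, np.pi - dtheta) == pytest.approx(phi, abs=1e-6) or \
            dtheta == pytest.approx(phi, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse(np.zeros((4, 2)))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)


class TestClassifyView:
    def test_near_circular_is_top(self):
        from nmfpick import EllipseParams

        assert classify_view(EllipseParams(0, 0, 10, 9, 0.0)) == "top"

    def test_elongated_is_side(self):
        from nmfpick import EllipseParams

        assert classify_view(EllipseParams(0, 0, 30, 8, 0.0)) == "side"

    def test_threshold_boundary_goes_to_side(self):
        from nmfpick import EllipseParams

        assert classify_view(EllipseParams(0, 0, 15, 10, 0.0), 1.5) == "side"
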