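"""Window geometry, strain estimation, retrodeformation and masking."""

import numpy as np
import pytest

from congalines import (
    StrainEstimate,
    SurfaceMap,
    Window,
    estimate_strain,
    mask_holes,
    retrodeform,
)
from congalines.errors import (
    InsufficientDataError,
    InvalidMaskError,
    InvalidStrainError,
    InvalidWindowError,
)
from congalines.surfaces import area, forward_stretch

from conftest import rect_window


class TestWindow:
    def test_unit_square_area(self, unit_window):
        assert area(unit_window) == pytest.approx(1.0)

    def test_square_with_hole_area(self):
        w = Window(
            np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float),
            holes=[np.array([[0.5, 0.5], [1.0, 0.5], [1.0, 1.0], [0.5, 1.0]])],
        )
        assert area(w) == pytest.approx(3.75)

    def test_area_additivity_with_holes(self):
        holes = [
            np.array([[0.1, 0.1], [0.4, 0.1], [0.4, 0.3], [0.1, 0.3]]),
            np.array([[1.2, 1.2], [1.7, 1.3], [1.5, 1.8]]),
        ]
        w = Window(np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float), holes)
        hole_area = sum(Window(h).area for h in holes)
        assert w.area + hole_area == pytest.approx(4.0, rel=1e-9)

    def test_random_polygon_area_matches_dart_throwing(self):
        """Shoelace-style area agrees with a rejection-sampling estimate."""
        rng = np.random.default_rng(7)
        # star-shaped simple polygon around a centre
        ang = np.sort(rng.uniform(0, 2 * np.pi, 9))
        rad = rng.uniform(0.4, 1.0, 9)
        poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        w = Window(poly)
        n = 200_000
        x = rng.uniform(-1, 1, n)
        y = rng.uniform(-1, 1, n)
        phat = w.contains(x, y).mean()
        est = phat * 4.0
        se = 4.0 * np.sqrt(phat * (1 - phat) / n)
        assert abs(w.area - est) <= 3 * se

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(InvalidWindowError):
            Window(np.array([[0, 0], [1, 1]], dtype=float))
        with pytest.raises(InvalidWindowError):
            Window(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))  # zero area

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(InvalidWindowError):
            Window(bowtie)

    def test_boundary_points_are_inside(self, unit_window):
        # closed exterior: boundary counts as inside
        assert unit_window.contains([0.0], [0.5])[0]
        assert unit_window.contains([1.0], [1.0])[0]
        assert not unit_window.contains([1.0001], [0.5])[0]

    def test_point_outside_window_rejected(self, unit_window):
        with pytest.raises(InvalidWindowError):
            SurfaceMap(points=np.array([[2.0, 0.5]]), window=unit_window)


class TestStrain:
    def test_circular_discs_flagged_undefined(self):
        discs = np.array([[0, 0, 0.01, 0.01, 10.0], [1, 1, 0.02, 0.02, 120.0]])
        s = estimate_strain(discs)
        assert s.R == pytest.approx(1.0)
        assert not s.phi_defined

    def test_uniform_ellipses_recovered_exactly(self):
        discs = np.array([[0, 0, 0.02, 0.01, 30.0], [1, 0, 0.04, 0.02, 30.0]])
        s = estimate_strain(discs)
        assert s.R == pytest.approx(2.0)
        assert s.phi_deg == pytest.approx(30.0)

    def test_azimuth_mean_wraps_orientation_period(self):
        # 170 and 10 degrees straddle the 0/180 wrap: mean is 0, not 90
        discs = np.array([[0, 0, 2.0, 1.0, 170.0], [0, 0, 2.0, 1.0, 10.0]])
        assert estimate_strain(discs).phi_deg == pytest.approx(0.0, abs=1e-9)

    def test_empty_disc_list_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_strain(np.empty((0, 5)))

    def test_recovers_known_stretch_from_simulated_circles(self):
        """Forward-stretch simulated circular discs, then invert the strain."""
        rng = np.random.default_rng(3)
        R0, phi0 = 1.8, 45.0
        centres = rng.uniform(0.3, 1.7, (40, 2))
        radii = rng.uniform(0.005, 0.02, 40)
        discs = np.column_stack(
            [centres, radii, radii, np.zeros(40)]
        )
        w = rect_window(2.0)
        surf = SurfaceMap(points=centres, window=w, discs=discs)
        stretched = forward_stretch(surf, StrainEstimate(R0, phi0))
        est = estimate_strain(stretched.discs)
        assert est.R == pytest.approx(R0, rel=0.05)
        assert min(abs(est.phi_deg - phi0), 180 - abs(est.phi_deg - phi0)) < 3.0


class TestRetrodeform:
    def test_identity_strain_is_noop(self, unit_window):
        surf = SurfaceMap(points=np.array([[0.3, 0.4]]), window=unit_window)
        out = retrodeform(surf, StrainEstimate(1.0, 0.0, phi_defined=False))
        np.testing.assert_array_equal(out.points, surf.points)

    def test_axis_aligned_compression(self):
        w = rect_window(2.0)
        surf = SurfaceMap(points=np.array([[1.0, 0.0]]), window=w)
        out = retrodeform(surf, StrainEstimate(4.0, 0.0))
        # x shrinks by 1/sqrt(4), y = 0 stays on the axis
        assert out.points[0, 0] == pytest.approx(0.5)
        assert out.points[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(11)
        w = rect_window(2.0)
        pts = rng.uniform(0.1, 1.9, (50, 2))
        surf = SurfaceMap(points=pts, window=w)
        strain = StrainEstimate(1.7, 63.0)
        back = retrodeform(forward_stretch(surf, strain), strain)
        np.testing.assert_allclose(back.points, pts, atol=1e-9)
        np.testing.assert_allclose(back.window.exterior, w.exterior, atol=1e-9)

    def test_preserves_area_and_count(self):
        rng = np.random.default_rng(13)
        w = rect_window(2.0)
        pts = rng.uniform(0.1, 1.9, (80, 2))
        surf = SurfaceMap(points=pts, window=w)
        out = retrodeform(surf, StrainEstimate(2.5, 20.0))
        assert out.n == surf.n
        assert out.window.area == pytest.approx(w.area, rel=1e-9)

    def test_restores_stretched_discs_to_circles(self):
        rng = np.random.default_rng(5)
        radii = rng.uniform(0.005, 0.02, 30)
        discs = np.column_stack(
            [rng.uniform(0.5, 1.5, (30, 2)), radii, radii, np.zeros(30)]
        )
        surf = SurfaceMap(
            points=discs[:, :2], window=rect_window(2.0), discs=discs
        )
        strain = StrainEstimate(1.8, 45.0)
        stretched = forward_stretch(surf, strain)
        restored = retrodeform(stretched, estimate_strain(stretched.discs))
        ratios = restored.discs[:, 2] / restored.discs[:, 3]
        assert np.mean(ratios) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_strain_rejected(self):
        with pytest.raises(InvalidStrainError):
            StrainEstimate(0.8, 0.0)


class TestMaskHoles:
    def test_empty_hole_list_is_noop(self, unit_window):
        surf = SurfaceMap(points=np.array([[0.5, 0.5]]), window=unit_window)
        assert mask_holes(surf, []) is surf

    def test_points_in_hole_removed_and_area_reduced(self):
        w = rect_window(2.0)
        pts = np.array(
            [[0.1, 0.1], [0.2, 0.2], [1.1, 1.1], [1.2, 1.2], [1.3, 1.1],
             [1.9, 0.1], [0.1, 1.9], [0.5, 1.0], [1.0, 0.5], [1.8, 1.8]]
        )
        hole = np.array([[1.0, 1.0], [1.5, 1.0], [1.5, 1.5], [1.0, 1.5]])
        surf = SurfaceMap(
            points=pts, window=w, marks={"taxon": np.array(list("abcdefghij"))}
        )
        out = mask_holes(surf, [hole])
        assert out.n == 7
        assert out.window.area == pytest.approx(4.0 - 0.25)
        assert list(out.marks["taxon"]) == list("abfghij")

    def test_idempotent_for_fixed_holes(self):
        w = rect_window(2.0)
        rng = np.random.default_rng(17)
        surf = SurfaceMap(points=rng.uniform(0, 2, (100, 2)), window=w)
        hole = [np.array([[0.5, 0.5], [1.0, 0.5], [1.0, 1.0], [0.5, 1.0]])]
        once = mask_holes(surf, hole)
        twice = mask_holes(once, hole)
        assert twice.n == once.n
        assert twice.window.area == pytest.approx(once.window.area, rel=1e-12)

    def test_hole_outside_exterior_rejected(self, unit_window):
        surf = SurfaceMap(points=np.array([[0.5, 0.5]]), window=unit_window)
        with pytest.raises(InvalidMaskError):
            mask_holes(surf, [np.array([[2, 2], [3, 2], [3, 3], [2, 3]])])

    def test_csr_thinning_fraction_matches_hole_area(self):
        """Masking 10% of a CSR surface removes ~10% of points on average."""
        from congalines import CsrParams, simulate_csr

        w = rect_window(2.0)
        hole = [np.array([[0.2, 0.2], [0.85, 0.2], [0.85, 0.85], [0.2, 0.85]])]
        hole_frac = 0.65**2 / 4.0
        kept = []
        for i in range(200):
            surf = simulate_csr(CsrParams(100.0), w, seed=900 + i)
            if surf.n:
                kept.append(mask_holes(surf, hole).n / surf.n)
        mean_kept = np.mean(kept)
        se = np.std(kept, ddof=1) / np.sqrt(len(kept))
        assert abs(mean_kept - (1 - hole_frac)) <= 3 * se
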