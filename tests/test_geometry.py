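"""Frame-wise geometric descriptors: closed forms, oracles and invariants."""

import numpy as np
import pytest

from plaquetrend.errors import (
    AnchorError,
    GeometryInconsistencyError,
    InvalidContourError,
)
from plaquetrend.geometry import (
    Contour,
    compute_frame_features,
    contour_basic_metrics,
    curvature_profile,
    diameter_extremes,
    eccentricity_features,
    frame_areas,
    plaque_distribution_features,
    shape_complexity_features,
)

from conftest import random_frame


def circle(r=1.0, n=360, center=(0.0, 0.0), role="lumen"):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return Contour(pts, role)


class TestBasicMetrics:
    def test_unit_square(self):
        m = contour_basic_metrics(Contour([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert m.area == pytest.approx(1.0)
        assert m.perimeter == pytest.approx(4.0)
        assert m.centroid == pytest.approx([0.5, 0.5])

    def test_regular_360gon_area(self):
        # closed form: (n/2)·sin(2π/n) for circumradius 1
        m = contour_basic_metrics(circle(1.0, 360))
        assert m.area == pytest.approx(180.0 * np.sin(2.0 * np.pi / 360.0), abs=1e-12)
        assert m.r_fit == pytest.approx(1.0, abs=1e-9)

    def test_orientation_normalized(self):
        cw = Contour([(0, 0), (0, 1), (1, 1), (1, 0)])  # clockwise input
        assert contour_basic_metrics(cw).area > 0

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0), (1, 1)],  # 2 vertices
            [(0, 0), (1, 1), (1, 0), (0, 1)],  # bow-tie self-intersection
            [(0, 0), (1, 0), (2, 0)],  # collinear, zero area
        ],
    )
    def test_invalid_contours_rejected(self, points):
        with pytest.raises(InvalidContourError):
            Contour(points)


class TestAreas:
    def test_plaque_area_and_burden(self):
        out = frame_areas(circle(1.0, 360, role="lumen"), circle(2.0, 360, role="vessel"))
        assert out["plaque_area"] == pytest.approx(out["vessel_area"] - out["lumen_area"])
        assert out["pb"] == pytest.approx(75.0, abs=1e-9)

    def test_identical_contours_no_plaque(self):
        c = circle(1.5, 180)
        out = frame_areas(c, Contour(c.points, "vessel"))
        assert out["plaque_area"] == pytest.approx(0.0, abs=1e-12)
        assert out["pb"] == pytest.approx(0.0, abs=1e-12)

    def test_lumen_larger_than_vessel_rejected(self):
        with pytest.raises(GeometryInconsistencyError):
            frame_areas(circle(2.0, 180), circle(1.0, 180, role="vessel"))


class TestDiameters:
    def test_circle_through_center(self):
        d = diameter_extremes(circle(1.0, 720), (0.0, 0.0))
        assert d["d_min"] == pytest.approx(2.0, rel=1e-4)
        assert d["d_max"] == pytest.approx(2.0, rel=1e-4)

    def test_ellipse_axes(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ell = Contour(np.column_stack([2 * np.cos(th), np.sin(th)]))
        coarse = diameter_extremes(ell, (0, 0), n_directions=360)
        dense = diameter_extremes(ell, (0, 0), n_directions=3600)
        assert coarse["d_min"] == pytest.approx(dense["d_min"], rel=1e-2)
        assert coarse["d_max"] == pytest.approx(dense["d_max"], rel=1e-2)
        assert dense["d_min"] == pytest.approx(2.0, rel=1e-3)
        assert dense["d_max"] == pytest.approx(4.0, rel=1e-3)

    def test_anchor_outside_rejected(self):
        with pytest.raises(AnchorError):
            diameter_extremes(circle(1.0, 90), (5.0, 0.0))


class TestEccentricity:
    def test_concentric_circles_symmetric(self):
        out = eccentricity_features(
            circle(1.0, 360), circle(2.0, 360, role="vessel"), (0.0, 0.0)
        )
        assert out["xi_l"] == pytest.approx(1.0, abs=1e-3)
        assert out["xi_v"] == pytest.approx(1.0, abs=1e-3)
        assert out["xi_p"] == pytest.approx(0.0, abs=1e-9)
        assert out["psi_l"] == pytest.approx(0.0, abs=0.02)

    def test_centroid_offset_normalization(self):
        # lumen r=1 at (0.5, 0) inside vessel r=2 at origin: offset 0.5 over
        # mean lumen diameter 2
        out = eccentricity_features(
            circle(1.0, 360, center=(0.5, 0.0)), circle(2.0, 360, role="vessel"), (0.0, 0.0)
        )
        assert out["xi_p"] == pytest.approx(0.25, abs=1e-4)

    def test_two_to_one_ellipse_eccentricity(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ell = Contour(np.column_stack([2 * np.cos(th), np.sin(th)]))
        out = eccentricity_features(ell, circle(4.0, 360, role="vessel"), (0.0, 0.0))
        assert out["psi_l"] == pytest.approx(np.sqrt(3.0) / 2.0, abs=1e-3)


class TestPlaqueDistribution:
    def test_uniform_annulus(self):
        out = plaque_distribution_features(circle(1.0, 360), circle(2.0, 360, role="vessel"))
        assert out["rho_l"] == 100.0
        assert out["rho_v"] == 100.0
        assert out["thickness_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_thin_annulus_below_threshold(self):
        out = plaque_distribution_features(circle(1.0, 360), circle(1.1, 360, role="vessel"))
        assert out["rho_l"] == 0.0
        assert out["rho_v"] == 0.0

    def test_eccentric_lumen_matches_dense_oracle(self):
        lumen = circle(1.0, 360, center=(0.5, 0.0))
        vessel = circle(2.0, 360, role="vessel")
        coarse = plaque_distribution_features(lumen, vessel, n_angles=360)
        dense = plaque_distribution_features(lumen, vessel, n_angles=3600)
        for key in coarse:
            assert coarse[key] == pytest.approx(dense[key], rel=0.01, abs=0.5)


class TestShapeComplexity:
    def test_circle_roughness_is_one(self):
        out = shape_complexity_features(circle(2.0, 720))
        assert out["kappa"] == pytest.approx(1.0, abs=1e-3)

    def test_circle_circularity_and_irregularity_converge(self):
        prev_phi_gap, prev_tau = None, None
        for n in (64, 128, 256, 512):
            out = shape_complexity_features(circle(1.0, n))
            gap = abs(out["phi"] - 1.0)
            if prev_phi_gap is not None:
                assert gap <= prev_phi_gap + 1e-12
                assert out["tau"] <= prev_tau + 1e-12
            prev_phi_gap, prev_tau = gap, out["tau"]

    def test_square_circularity(self):
        # unit square resampled densely: 4πA/P² = π/4
        th_square = Contour([(0, 0), (1, 0), (1, 1), (0, 1)])
        out = shape_complexity_features(th_square, n_resample=400)
        assert out["phi"] == pytest.approx(np.pi / 4.0, abs=1e-3)

    def test_curvature_profile_sums_to_perimeter(self):
        rng = np.random.default_rng(0)
        lumen, _ = random_frame(rng)
        prof = curvature_profile(lumen)
        perimeter = contour_basic_metrics(lumen).perimeter
        assert np.sum(prof.delta_l) == pytest.approx(perimeter, rel=1e-9)
        assert prof.varkappa.size == prof.delta_l.size

    def test_roughness_stable_under_annotation_density(self):
        # the arclength resampling makes κ nearly independent of how densely
        # the same smooth boundary was annotated
        rng = np.random.default_rng(1)
        for _ in range(5):
            dense_lumen, _ = random_frame(rng, n_vertices=1024)
            sparse = Contour(dense_lumen.points[::8], "lumen")  # 128 vertices
            k_dense = shape_complexity_features(dense_lumen)["kappa"]
            k_sparse = shape_complexity_features(sparse)["kappa"]
            assert k_sparse == pytest.approx(k_dense, rel=0.05)


class TestFrameFeatures:
    def test_concentric_composition(self):
        ff = compute_frame_features(circle(1.0, 360), circle(2.0, 360, role="vessel"))
        assert ff.pb == pytest.approx(75.0, abs=1e-9)
        assert ff.psi_l == pytest.approx(0.0, abs=0.02)
        assert ff.phi_l == pytest.approx(1.0, abs=1e-3)
        assert ff.rho_l == 100.0

    def test_no_plaque_thickness_ratio_convention(self):
        c = circle(1.5, 360)
        ff = compute_frame_features(c, Contour(c.points, "vessel"))
        assert ff.plaque_area == pytest.approx(0.0, abs=1e-12)
        assert ff.thickness_ratio == 1.0

    def test_invariants_on_random_frames(self):
        # FrameFeatures.__post_init__ enforces the invariants; constructing
        # features for many random frames must never raise
        rng = np.random.default_rng(2)
        for _ in range(100):
            lumen, vessel = random_frame(rng)
            ff = compute_frame_features(lumen, vessel)
            assert ff.plaque_area >= 0.0
            assert 1.0 <= ff.thickness_ratio

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        lumen, vessel = random_frame(rng)
        a = compute_frame_features(lumen, vessel)
        b = compute_frame_features(lumen.scaled(2.5), vessel.scaled(2.5))
        for name in ("pb", "xi_l", "xi_v", "xi_p", "psi_l", "psi_v", "phi_l",
                     "phi_v", "rho_l", "rho_v", "thickness_ratio", "kappa_l", "kappa_v"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9, abs=1e-9), name
        # dimensional features scale by their units
        assert b.lumen_area == pytest.approx(a.lumen_area * 2.5**2, rel=1e-9)
        assert b.tau_l == pytest.approx(a.tau_l / 2.5, rel=1e-6)
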