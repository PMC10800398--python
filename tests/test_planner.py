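"""Puncture planning: plane fits, interspace frame, axes, barrels."""

import dataclasses

import numpy as np
import pytest

from spineosteo.anatomy import SubjectParams, generate_phantom
from spineosteo.planner import (ALLOWED_ANGLES, Plane, TrephinePlan,
                                build_interspace_frame, fit_endplate_plane,
                                fit_plane_to_points, plan_frame, plan_tools,
                                trephine_axis, trephine_cylinder)


class TestPlaneFit:
    def test_flat_plane_exact(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, (50, 2)),
                               np.full(50, 10.0)])
        plane = fit_plane_to_points(pts)
        assert plane.normal == pytest.approx([0, 0, 1])
        assert plane.point[2] == pytest.approx(10.0)

    def test_sinusoidal_roughness_within_one_degree(self):
        x, y = np.meshgrid(np.linspace(-10, 10, 21),
                           np.linspace(-10, 10, 21))
        z = 0.2 * np.sin(x)
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        plane = fit_plane_to_points(pts)
        angle = np.degrees(np.arccos(abs(plane.normal @ [0, 0, 1.0])))
        # cross-check against an independently computed SVD best fit
        c = pts - pts.mean(axis=0)
        normal_svd = np.linalg.svd(c)[2][2]
        assert angle < 1.0
        assert abs(abs(plane.normal @ normal_svd) - 1) < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_plane_to_points(pts)

    def test_phantom_endplate_rms(self, default_phantom):
        plane = fit_endplate_plane(default_phantom, "endplate_L5_superior")
        verts = default_phantom.region_mesh("endplate_L5_superior").vertices
        rms = np.sqrt(np.mean(plane.signed_distance(verts) ** 2))
        assert rms <= 0.5  # mm; the endplate is a thin slab


class TestInterspaceFrame:
    def test_center_is_landmark_midpoint(self, default_phantom,
                                         default_frame):
        lm = default_phantom.landmarks
        hi = lm["endplate_L4_inferior_posterior_midpoint"]
        lo = lm["endplate_L5_superior_posterior_midpoint"]
        assert default_frame.center == pytest.approx(0.5 * (hi + lo))

    def test_reference_plane_parallel_to_l5_superior(self, default_phantom,
                                                     default_frame):
        l5 = fit_endplate_plane(default_phantom, "endplate_L5_superior")
        assert abs(default_frame.reference_plane.normal @ l5.normal) == \
            pytest.approx(1.0, abs=1e-9)

    def test_axes_orthonormal_in_plane(self, default_frame):
        n = default_frame.reference_plane.normal
        c = default_frame.central_axis
        l = default_frame.lateral_axis
        assert abs(c @ n) < 1e-9
        assert abs(l @ n) < 1e-9
        assert abs(c @ l) < 1e-9
        assert np.linalg.norm(c) == pytest.approx(1.0)

    def test_missing_landmark_raises(self, default_phantom):
        broken = dataclasses.replace(
            default_phantom,
            landmarks={k: v for k, v in default_phantom.landmarks.items()
                       if "posterior_midpoint" not in k})
        l5 = fit_endplate_plane(default_phantom, "endplate_L5_superior")
        with pytest.raises(KeyError):
            build_interspace_frame(broken, l5, l5)

    def test_center_near_disc_posterior_edge(self, default_phantom,
                                             default_frame):
        b_d = (default_phantom.params.vertebral_body_depth / 2.0
               * np.sqrt(default_phantom.params
                         .disc_to_vertebra_area_fraction))
        assert default_frame.center[1] == pytest.approx(-b_d, abs=1.0)


class TestTrephineAxis:
    def test_zero_angle_is_central_axis(self, default_frame):
        point, direction = trephine_axis(default_frame, 0,
                                         allow_nonstandard=True)
        assert direction == pytest.approx(-default_frame.central_axis)
        assert point == pytest.approx(default_frame.center)

    @pytest.mark.parametrize("angle", ALLOWED_ANGLES)
    def test_in_plane_signed_angle(self, default_frame, angle):
        _, d = trephine_axis(default_frame, angle)
        n = default_frame.reference_plane.normal
        assert abs(d @ n) < 1e-9
        outward = -d
        got = np.degrees(np.arctan2(outward @ default_frame.lateral_axis,
                                    outward @ default_frame.central_axis))
        assert got == pytest.approx(angle, abs=1e-9)

    def test_second_attempt_offset(self, default_frame):
        _, d1 = trephine_axis(default_frame, 60, attempt=1)
        _, d2 = trephine_axis(default_frame, 60, attempt=2)
        between = np.degrees(np.arccos(np.clip(d1 @ d2, -1, 1)))
        assert between == pytest.approx(5.0, abs=1e-9)

    def test_span_between_extreme_angles(self, default_frame):
        _, d20 = trephine_axis(default_frame, 20)
        _, d70 = trephine_axis(default_frame, 70)
        span = np.degrees(np.arccos(np.clip(d20 @ d70, -1, 1)))
        assert span == pytest.approx(50.0, abs=1e-9)

    def test_axes_coplanar(self, default_frame):
        n = default_frame.reference_plane.normal
        for angle in ALLOWED_ANGLES:
            for attempt in (1, 2):
                _, d = trephine_axis(default_frame, angle, attempt)
                assert abs(d @ n) < 1e-9

    def test_disallowed_angle_rejected(self, default_frame):
        with pytest.raises(ValueError):
            trephine_axis(default_frame, 45)

    def test_left_side_mirror_symmetry(self, default_frame):
        """Mirroring about mid-sagittal: left-side axes are reflections."""
        for angle in ALLOWED_ANGLES:
            _, d_right = trephine_axis(default_frame, angle, side="right")
            _, d_left = trephine_axis(default_frame, angle, side="left")
            mirrored = d_right * np.array([-1.0, 1.0, 1.0])
            assert d_left == pytest.approx(mirrored, abs=1e-12)


class TestTrephineCylinder:
    def test_volume_closed_form(self, default_frame):
        axis = trephine_axis(default_frame, 50)
        tool = trephine_cylinder(axis, 8, length=120.0)
        expected = np.pi * 16.0 * 120.0
        assert tool.volume == pytest.approx(expected, rel=0.005)

    def test_diameter_scaling(self, default_frame):
        axis = trephine_axis(default_frame, 50)
        v7 = trephine_cylinder(axis, 7).volume
        v9 = trephine_cylinder(axis, 9).volume
        assert v7 / v9 == pytest.approx((7 / 9) ** 2, rel=1e-6)

    def test_centroid_on_axis(self, default_frame):
        point, direction = trephine_axis(default_frame, 50)
        tool = trephine_cylinder((point, direction), 8)
        centroid = tool.vertices.mean(axis=0)
        rel = centroid - point
        off_axis = rel - (rel @ direction) * direction
        assert np.linalg.norm(off_axis) < 1e-6

    def test_nonstandard_diameter_needs_flag(self, default_frame):
        axis = trephine_axis(default_frame, 50)
        with pytest.raises(ValueError):
            trephine_cylinder(axis, 10)
        tool = trephine_cylinder(axis, 10, allow_nonstandard=True)
        assert tool.volume > 0

    def test_plan_tools_counts(self, default_frame):
        plan = TrephinePlan(angle_deg=50, diameter_mm=8, attempts=2)
        tools = plan_tools(default_frame, plan)
        assert len(tools) == 2

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            TrephinePlan(angle_deg=45, diameter_mm=8).validate()
        with pytest.raises(ValueError):
            TrephinePlan(angle_deg=50, diameter_mm=8, attempts=3).validate()
        assert TrephinePlan(angle_deg=20, diameter_mm=7).group == "PEID"
        assert TrephinePlan(angle_deg=50, diameter_mm=7).group == "PTED"
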