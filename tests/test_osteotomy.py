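"""Boolean resection volumes, the Monte-Carlo oracle, and resected models."""

import numpy as np
import pytest

from spineosteo.anatomy import SubjectParams, generate_phantom
from spineosteo.convex import ConvexSolid, RegionSolid, rectangle_polygon
from spineosteo.osteotomy import (_union_volume, intersect_volume,
                                  mesh_intersect_volume, monte_carlo_volume,
                                  resect, run_volume_experiment)
from spineosteo.planner import TrephinePlan, plan_frame, plan_tools


def cylinder_solid(diameter, length, n=64):
    theta = 2 * np.pi * np.arange(n) / n
    r = diameter / 2.0 / np.sqrt(np.sinc(2 * np.pi / n / np.pi))
    poly = r * np.column_stack([np.cos(theta), np.sin(theta)])
    return ConvexSolid.from_extrusion(poly, 0, length)


class TestUnionVolume:
    def test_cylinder_inside_cube(self):
        cube = ConvexSolid.from_extrusion(rectangle_polygon(50, 50), -25, 25)
        region = RegionSolid("cube", pos=[cube])
        tool = cylinder_solid(8, 10)
        v = _union_volume(region, [tool])
        assert v == pytest.approx(np.pi * 16 * 10, rel=0.005)

    def test_two_coincident_cylinders_idempotent(self):
        cube = ConvexSolid.from_extrusion(rectangle_polygon(50, 50), -25, 25)
        region = RegionSolid("cube", pos=[cube])
        tool = cylinder_solid(8, 10)
        v1 = _union_volume(region, [tool])
        v2 = _union_volume(region, [tool, tool])
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_mesh_path_matches_exact(self):
        cube = ConvexSolid.from_extrusion(rectangle_polygon(20, 20), -5, 5)
        tool = cylinder_solid(8, 30)
        # displace tool to protrude through the cube top
        t = np.eye(4)
        t[:3, 3] = [2.0, 1.0, -15.0]
        tool = tool.transformed(t)
        exact = cube.intersection_volume(tool)
        via_mesh = mesh_intersect_volume(cube.to_mesh(), tool)
        assert via_mesh == pytest.approx(exact, rel=1e-6)


class TestMonteCarloOracle:
    def test_identity_box(self, default_phantom):
        """Tool coincides with a bone-aligned box: estimate ~ exact."""
        frame_tools = [ConvexSolid.from_extrusion(
            rectangle_polygon(10, 10, (0, 0)), 10, 20)]
        mc = monte_carlo_volume(default_phantom, frame_tools,
                                n_samples=10**5, seed=0)
        exact, _, _ = intersect_volume(default_phantom, frame_tools)
        assert abs(exact - mc["estimate"]) <= 3 * mc["stderr"] + 1e-9

    def test_disjoint_tool_zero(self, default_phantom):
        far = [ConvexSolid.from_extrusion(rectangle_polygon(5, 5),
                                          500, 510)]
        mc = monte_carlo_volume(default_phantom, far, n_samples=10**4)
        assert mc["estimate"] == 0.0

    def test_minimum_samples_enforced(self, default_phantom, default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=8))
        with pytest.raises(ValueError):
            monte_carlo_volume(default_phantom, tools, n_samples=100)

    def test_boolean_within_oracle_error(self, default_phantom,
                                         default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=9))
        exact, _, _ = intersect_volume(default_phantom, tools)
        mc = monte_carlo_volume(default_phantom, tools, n_samples=10**6,
                                seed=5)
        assert abs(exact - mc["estimate"]) <= 3 * mc["stderr"]

    def test_seed_determinism(self, default_phantom, default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=30, diameter_mm=8))
        a = monte_carlo_volume(default_phantom, tools, 10**4, seed=9)
        b = monte_carlo_volume(default_phantom, tools, 10**4, seed=9)
        assert a == b


class TestResect:
    def test_disjoint_tool_leaves_model_unchanged(self, default_phantom):
        far = [ConvexSolid.from_extrusion(rectangle_polygon(5, 5),
                                          500, 510)]
        out, report = resect(default_phantom, far)
        assert report["modified_regions"] == {}
        assert report["removed_regions"] == []
        for name in default_phantom.regions:
            assert out.regions[name] is default_phantom.regions[name]

    def test_volume_conservation_per_region(self, default_phantom,
                                            default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=9,
                                        attempts=2))
        out, report = resect(default_phantom, tools)
        assert report["modified_regions"]
        for name in report["modified_regions"]:
            v0 = default_phantom.regions[name].volume
            cut = _union_volume(default_phantom.regions[name], tools)
            v1 = out.regions[name].volume
            assert v1 + cut == pytest.approx(v0, rel=0.01)

    def test_resected_meshes_watertight(self, default_phantom,
                                        default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=8))
        out, report = resect(default_phantom, tools)
        for name in report["modified_regions"]:
            mesh = out.regions[name].to_mesh()
            assert mesh.is_watertight, name
            assert mesh.volume > 0

    def test_engulfed_region_dropped_and_reported(self, default_phantom):
        cart = default_phantom.regions["facet_cartilage_L4L5_right"]
        verts = np.vstack([p.vertices for p in cart.pos])
        lo, hi = verts.min(axis=0) - 1, verts.max(axis=0) + 1
        big = ConvexSolid.from_extrusion(
            rectangle_polygon(hi[0] - lo[0], hi[1] - lo[1],
                              ((lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2)),
            lo[2], hi[2])
        out, report = resect(default_phantom, [big])
        assert "facet_cartilage_L4L5_right" in report["removed_regions"]
        assert "facet_cartilage_L4L5_right" not in out.regions


class TestIntersectVolume:
    def test_breakdown_sums_to_total(self, default_phantom, default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=9))
        total, breakdown, per_region = intersect_volume(default_phantom,
                                                        tools)
        assert total > 0
        assert sum(breakdown.values()) == pytest.approx(total, rel=0.01)
        assert sum(per_region.values()) == pytest.approx(total, rel=1e-9)

    def test_transforaminal_hits_the_facet_joint(self, default_phantom,
                                                 default_frame):
        """A 50-degree barrel transits the L4/5 joint: both processes cut."""
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=9))
        _, breakdown, _ = intersect_volume(default_phantom, tools)
        assert breakdown["facet_L5_superior"] > 0
        assert breakdown["facet_L4_inferior"] > 0
        assert breakdown["cartilage"] > 0

    def test_cartilage_flag(self, default_phantom, default_frame):
        tools = plan_tools(default_frame,
                           TrephinePlan(angle_deg=50, diameter_mm=9))
        with_c, _, _ = intersect_volume(default_phantom, tools,
                                        include_cartilage=True)
        without, _, _ = intersect_volume(default_phantom, tools,
                                         include_cartilage=False)
        assert with_c > without


class TestVolumeExperiment:
    @pytest.fixture(scope="class")
    def small_run(self):
        from spineosteo.anatomy import CohortSpec
        return run_volume_experiment(
            CohortSpec(n_subjects=2, master_seed=0),
            angles=(20, 50), diameters=(8,), attempts=(1, 2),
            tool_sections=32)

    def test_cardinality(self, small_run):
        assert len(small_run) == 2 * 2 * 1 * 2

    def test_attempts_monotone(self, small_run):
        piv = small_run.pivot_table(index=["subject", "angle_deg"],
                                    columns="attempts",
                                    values="removed_volume_mm3")
        assert (piv[2] >= piv[1] - 1e-9).all()

    def test_deterministic(self, small_run):
        from spineosteo.anatomy import CohortSpec
        again = run_volume_experiment(
            CohortSpec(n_subjects=2, master_seed=0),
            angles=(20, 50), diameters=(8,), attempts=(1, 2),
            tool_sections=32)
        assert small_run.equals(again)
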