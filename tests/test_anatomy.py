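"""Synthetic phantom: determinism, invariants, measured-spec recovery."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spineosteo.anatomy import (CohortSpec, SubjectParams, generate_phantom,
                                measure_area_fractions,
                                measure_cortical_thickness, sample_cohort)
from spineosteo.convex import ConvexSolid, superellipse_polygon


class TestGeneratePhantom:
    def test_deterministic_bit_identical(self, default_phantom):
        again = generate_phantom(SubjectParams(rng_seed=42))
        for name in default_phantom.regions:
            a = default_phantom.region_mesh(name)
            b = again.region_mesh(name)
            assert np.array_equal(a.vertices, b.vertices)
            assert np.array_equal(a.faces, b.faces)

    def test_all_meshes_watertight_positive(self, default_phantom):
        for name, mesh in default_phantom.meshes.items():
            assert mesh.is_watertight, name
            assert mesh.volume > 0, name

    def test_region_inventory(self, default_phantom):
        names = set(default_phantom.regions)
        for vert in ("L3", "L4", "L5"):
            for part in ("cortical", "cancellous", "posterior_elements"):
                assert f"{vert}_{part}" in names
        for disc in ("L3L4", "L4L5"):
            assert f"disc_{disc}_annulus" in names
            assert f"disc_{disc}_nucleus" in names
            for side in ("left", "right"):
                assert f"facet_cartilage_{disc}_{side}" in names
        for ep in ("L4_inferior", "L5_superior", "L3_inferior",
                   "L4_superior"):
            assert f"endplate_{ep}" in names

    def test_cancellous_inside_cortical_shell(self, default_phantom):
        rng = np.random.default_rng(3)
        for vert in ("L3", "L4", "L5"):
            cort = default_phantom.regions[f"{vert}_cortical"]
            canc = default_phantom.regions[f"{vert}_cancellous"]
            pts = canc.pos[0].vertices
            # cancellous boundary lies inside the cortical outer solid
            assert cort.pos[0].contains(pts).all()
            # and the two regions are disjoint
            probe = rng.uniform(pts.min(axis=0), pts.max(axis=0), (500, 3))
            both = cort.contains(probe) & canc.contains(probe)
            assert not both.any()

    def test_nucleus_inside_annulus_outer(self, default_phantom):
        for disc in ("L3L4", "L4L5"):
            ann = default_phantom.regions[f"disc_{disc}_annulus"]
            nuc = default_phantom.regions[f"disc_{disc}_nucleus"]
            assert ann.pos[0].contains(nuc.pos[0].vertices).all()

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError, match="cortical"):
            generate_phantom(SubjectParams(cortical_thickness=20.0))
        with pytest.raises(ValueError, match="nucleus_area_fraction"):
            generate_phantom(SubjectParams(nucleus_area_fraction=1.5))
        with pytest.raises(ValueError, match="cartilage"):
            generate_phantom(SubjectParams(cartilage_thickness=1.2))

    def test_posterior_parts_disjoint(self, default_phantom):
        """Convex parts tile each posterior region without double counting."""
        rng = np.random.default_rng(11)
        for vert in ("L4", "L5"):
            region = default_phantom.regions[f"{vert}_posterior_elements"]
            verts = np.vstack([p.vertices for p in region.pos])
            pts = rng.uniform(verts.min(axis=0), verts.max(axis=0),
                              (4000, 3))
            counts = sum(p.contains(pts, tol=-1e-9).astype(int)
                         for p in region.pos)
            assert counts.max() <= 1


class TestMeasurements:
    def test_default_fractions(self, default_phantom):
        fr = measure_area_fractions(default_phantom)
        assert fr["nucleus_over_disc"] == pytest.approx(0.40, abs=0.008)
        assert fr["disc_over_vertebra"] == pytest.approx(0.95, abs=0.02)
        assert fr["ap_offset_ratio"] == pytest.approx(1.62, rel=0.05)

    def test_cortical_thickness_raycast(self, default_phantom):
        thick = measure_cortical_thickness(default_phantom)
        assert 0.9 <= thick <= 1.1

    def test_concentric_circles_closed_form(self, default_phantom):
        """Toy disc: concentric circles, nucleus r, annulus r*sqrt(2.5)."""
        import dataclasses as dc
        model = dc.replace(default_phantom)
        r = 10.0
        circle = superellipse_polygon(r, r, 2.0, 128)
        from spineosteo.convex import RegionSolid
        outer = ConvexSolid.from_extrusion(circle * np.sqrt(2.5), -4, 4)
        inner = ConvexSolid.from_extrusion(circle, -4, 4)
        regions = dict(model.regions)
        regions["disc_L4L5_annulus"] = RegionSolid(
            "disc_L4L5_annulus", pos=[outer], neg=[inner])
        regions["disc_L4L5_nucleus"] = RegionSolid(
            "disc_L4L5_nucleus", pos=[inner])
        toy = dc.replace(model, regions=regions, _mesh_cache={})
        fr = measure_area_fractions(toy)
        assert fr["nucleus_over_disc"] == pytest.approx(0.4, abs=1e-3)
        assert fr["ap_offset_ratio"] == pytest.approx(1.0, abs=1e-3)

    @given(st.floats(0.3, 0.5), st.floats(1.2, 2.0))
    @settings(max_examples=5, deadline=None)
    def test_spec_recovery_property(self, nucleus_frac, ap_ratio):
        """Measured fractions track requested parameters (recovery)."""
        from hypothesis import assume
        # geometric feasibility: the offset nucleus must stay inside the
        # annulus, i.e. sqrt(fraction) < 2 / (1 + ratio)
        assume(nucleus_frac < 0.95 * (2.0 / (1.0 + ap_ratio)) ** 2)
        params = SubjectParams(nucleus_area_fraction=nucleus_frac,
                               ap_offset_ratio=ap_ratio)
        fr = measure_area_fractions(generate_phantom(params))
        assert fr["nucleus_over_disc"] == pytest.approx(nucleus_frac,
                                                        rel=0.02)
        assert fr["ap_offset_ratio"] == pytest.approx(ap_ratio, rel=0.05)


class TestCohort:
    def test_zero_cv_identical(self):
        spec = CohortSpec(n_subjects=5, jitter={}, master_seed=1)
        subjects = sample_cohort(spec)
        base = dataclasses.asdict(SubjectParams())
        for s in subjects:
            d = dataclasses.asdict(s)
            d.pop("rng_seed")
            base_d = dict(base)
            base_d.pop("rng_seed")
            assert d == base_d

    def test_sample_cv_in_band(self):
        spec = CohortSpec(n_subjects=25,
                          jitter={"vertebral_body_width": 0.05},
                          master_seed=7)
        widths = [s.vertebral_body_width for s in sample_cohort(spec)]
        cv = np.std(widths, ddof=1) / np.mean(widths)
        assert 0.02 <= cv <= 0.09

    def test_deterministic_under_master_seed(self):
        a = sample_cohort(CohortSpec(n_subjects=4, master_seed=3))
        b = sample_cohort(CohortSpec(n_subjects=4, master_seed=3))
        assert a == b

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(CohortSpec(n_subjects=1))

    def test_unknown_jitter_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            sample_cohort(CohortSpec(jitter={"femur_length": 0.1}))
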