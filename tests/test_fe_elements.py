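"""Element-level FE verification against closed-form mechanics."""

import numpy as np
import pytest

from spineosteo.fe.mesh import box_fe_model, graded_levels, lattice_tets
from spineosteo.fe.model import FEModel, Truss
from spineosteo.fe.solve import (LoadCase, assemble_stiffness,
                                 build_load_vector, compute_rom,
                                 compute_von_mises, factorize,
                                 fit_rigid_rotation, isotropic_C,
                                 reaction_residual, _solve_fixed,
                                 _truss_matrix)


def solve(fem, f):
    K = assemble_stiffness(fem)
    op = factorize(fem, K)
    return K, _solve_fixed(fem, op, f)


class TestLattice:
    def test_box_volume_conserved(self):
        mesh = box_fe_model(1, 1, 1, 4, 4, 4, 10.0, 0.3)
        assert mesh.tet_volumes.sum() == pytest.approx(1.0, rel=0.005)
        assert (mesh.tet_volumes > 0).all()

    def test_graded_levels_hit_breakpoints(self):
        levels = graded_levels([0.0, 1.0, 8.0, 9.0], 3.0)
        for b in (0.0, 1.0, 8.0, 9.0):
            assert np.min(np.abs(levels - b)) < 1e-9
        assert np.max(np.diff(levels)) <= 3.0 + 1e-9

    def test_conforming_shared_faces(self):
        """Adjacent cells share the full triangulated face (no T-joints)."""
        xs = ys = zs = np.array([0.0, 1.0, 2.0])
        mask = np.ones((2, 2, 2), dtype=bool)
        nodes, tets, _, _ = lattice_tets(xs, ys, zs, mask)
        faces = np.sort(tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3],
                                 [0, 1, 2]]], axis=2).reshape(-1, 3)
        _, counts = np.unique(faces, axis=0, return_counts=True)
        assert counts.max() == 2  # interior faces matched exactly twice


class TestSolidElements:
    def test_axial_bar_FL_over_EA(self):
        bar = box_fe_model(2, 2, 20, 2, 2, 10, young=100.0, poisson=0.0)
        fem = FEModel(mesh=bar, trusses=[], springs=[],
                      fixed_nodes=bar.node_sets["fixed"],
                      load_nodes=bar.node_sets["load"])
        f = np.zeros(3 * len(bar.nodes))
        f[3 * fem.load_nodes + 2] = -10.0 / len(fem.load_nodes)
        K, u = solve(fem, f)
        tip = u.reshape(-1, 3)[fem.load_nodes, 2].mean()
        assert tip == pytest.approx(-10.0 * 20 / (100.0 * 4), rel=0.01)
        assert reaction_residual(fem, K, u, f) < 1e-6

    def test_zero_load_zero_displacement(self):
        bar = box_fe_model(1, 1, 4, 1, 1, 4, 50.0, 0.3)
        fem = FEModel(mesh=bar, trusses=[], springs=[],
                      fixed_nodes=bar.node_sets["fixed"],
                      load_nodes=bar.node_sets["load"])
        _, u = solve(fem, np.zeros(3 * len(bar.nodes)))
        assert np.all(u == 0.0)

    def test_patch_linear_field_reproduced(self):
        """Distorted mesh reproduces an arbitrary linear field exactly."""
        mesh = box_fe_model(2, 2, 2, 2, 2, 2, 7.0, 0.3)
        rng = np.random.default_rng(0)
        interior = [i for i, p in enumerate(mesh.nodes)
                    if all(1e-9 < c < 2 - 1e-9 for c in p)]
        mesh.nodes[interior] += rng.uniform(-0.15, 0.15,
                                            (len(interior), 3))
        fem = FEModel(mesh=mesh, trusses=[], springs=[],
                      fixed_nodes=np.array([0]),
                      load_nodes=np.array([len(mesh.nodes) - 1]))
        A = np.array([[1e-3, 2e-4, 0.0],
                      [0.0, -5e-4, 3e-4],
                      [2e-4, 0.0, 8e-4]])
        ub = (mesh.nodes @ A.T).ravel()
        K = assemble_stiffness(fem)
        free = np.array([3 * i + c for i in interior for c in range(3)])
        fixed = np.setdiff1d(np.arange(3 * len(mesh.nodes)), free)
        from scipy.sparse.linalg import spsolve
        ui = spsolve(K[np.ix_(free, free)],
                     -K[np.ix_(free, fixed)] @ ub[fixed])
        assert np.abs(ui - ub[free]).max() < 1e-8

    def test_cantilever_beam_bending_stress(self):
        """Tip-loaded cantilever: max stress vs Euler-Bernoulli My/I."""
        L, b, h = 40.0, 4.0, 4.0
        E = 1000.0
        P = 5.0
        beam = box_fe_model(b, h, L, 4, 4, 40, young=E, poisson=0.0)
        fem = FEModel(mesh=beam, trusses=[], springs=[],
                      fixed_nodes=beam.node_sets["fixed"],
                      load_nodes=beam.node_sets["load"])
        f = np.zeros(3 * len(beam.nodes))
        f[3 * fem.load_nodes + 1] = P / len(fem.load_nodes)
        _, u = solve(fem, f)
        vm = compute_von_mises(fem, u)
        inertia = b * h ** 3 / 12.0
        sigma_max = P * L * (h / 2) / inertia
        # compare at one element-layer above the clamp where the section
        # stress is closest to beam theory
        zc = beam.nodes[beam.tets].mean(axis=1)[:, 2]
        layer = (zc > 2.0) & (zc < 4.0)
        got = vm[layer].max()
        lever = L - 3.0  # mid-layer lever arm
        expected = P * lever * (h / 2) / inertia
        assert got == pytest.approx(expected, rel=0.10)

    def test_von_mises_uniaxial_and_hydrostatic(self):
        C = isotropic_C(100.0, 0.0)
        # uniaxial: strain exx only, nu=0 -> sigma=(s,0,0) -> vm=|s|
        s = np.array([3.0, 0, 0, 0, 0, 0])
        sx, sy, sz, txy, tyz, tzx = s
        vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2
                            + (sz - sx) ** 2) + 3 * (txy**2 + tyz**2
                                                     + tzx**2))
        assert vm == pytest.approx(3.0)
        h = np.array([5.0, 5.0, 5.0, 0, 0, 0])
        sx, sy, sz, txy, tyz, tzx = h
        vmh = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2
                             + (sz - sx) ** 2) + 3 * (txy**2 + tyz**2
                                                      + tzx**2))
        assert vmh == pytest.approx(0.0)


class TestTruss:
    def test_axial_force_EA_delta_over_L(self):
        nodes = np.array([[0.0, 0, 0], [0.0, 0, 10.0]])
        k, dofs = _truss_matrix(nodes, 0, 1, ea=200.0)
        delta = 0.05
        u = np.zeros(6)
        u[5] = delta  # stretch along the bar
        force = (k @ u)[5]
        assert force == pytest.approx(200.0 * delta / 10.0)

    def test_zero_length_rejected(self):
        nodes = np.zeros((2, 3))
        with pytest.raises(ValueError):
            _truss_matrix(nodes, 0, 1, ea=1.0)


class TestRigidFitAndROM:
    def test_pure_rotation_recovered(self):
        rng = np.random.default_rng(2)
        x0 = rng.uniform(-10, 10, (50, 3))
        angle = np.radians(3.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(angle), -np.sin(angle)],
                      [0, np.sin(angle), np.cos(angle)]])
        R_fit = fit_rigid_rotation(x0, x0 @ R.T)
        got = np.degrees(np.arccos((np.trace(R_fit) - 1) / 2))
        assert got == pytest.approx(3.0, abs=1e-6)

    def test_pure_translation_zero_rotation(self):
        rng = np.random.default_rng(3)
        x0 = rng.uniform(-10, 10, (50, 3))
        R_fit = fit_rigid_rotation(x0, x0 + np.array([1.0, -2.0, 0.5]))
        got = np.degrees(np.arccos(np.clip((np.trace(R_fit) - 1) / 2,
                                           -1, 1)))
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_collinear_cloud_rejected(self):
        x0 = np.outer(np.arange(10.0), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            fit_rigid_rotation(x0, x0)

    def test_rom_synthetic_field(self):
        """ROM recovers a prescribed 3-degree rotation of L4 over L5."""
        mesh = box_fe_model(4, 4, 4, 2, 2, 2, 10.0, 0.3)
        mesh.node_sets["L4_body"] = np.arange(len(mesh.nodes) // 2)
        mesh.node_sets["L5_body"] = np.arange(len(mesh.nodes) // 2,
                                              len(mesh.nodes))
        fem = FEModel(mesh=mesh, trusses=[], springs=[],
                      fixed_nodes=np.array([0]),
                      load_nodes=np.array([1]))
        angle = np.radians(3.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(angle), -np.sin(angle)],
                      [0, np.sin(angle), np.cos(angle)]])
        u = np.zeros((len(mesh.nodes), 3))
        ids = mesh.node_sets["L4_body"]
        u[ids] = mesh.nodes[ids] @ R.T - mesh.nodes[ids]
        assert compute_rom(fem, u.ravel(), "L4L5") == pytest.approx(
            3.0, abs=1e-6)


class TestLoadVector:
    def test_pure_moment_is_self_equilibrated(self):
        mesh = box_fe_model(10, 10, 5, 4, 4, 2, 10.0, 0.3)
        fem = FEModel(mesh=mesh, trusses=[], springs=[],
                      fixed_nodes=mesh.node_sets["fixed"],
                      load_nodes=mesh.node_sets["load"])
        f = build_load_vector(fem, LoadCase(direction="flexion",
                                            follower_load=0.0,
                                            moment=10.0))
        forces = f.reshape(-1, 3)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9
        r = mesh.nodes - mesh.nodes[fem.load_nodes].mean(axis=0)
        moment = np.cross(r, forces).sum(axis=0)
        assert moment @ np.array([-1.0, 0, 0]) == pytest.approx(10_000.0)

    def test_follower_load_total(self):
        mesh = box_fe_model(10, 10, 5, 4, 4, 2, 10.0, 0.3)
        fem = FEModel(mesh=mesh, trusses=[], springs=[],
                      fixed_nodes=mesh.node_sets["fixed"],
                      load_nodes=mesh.node_sets["load"])
        f = build_load_vector(fem, LoadCase(direction="flexion",
                                            follower_load=400.0,
                                            moment=0.0))
        assert f.reshape(-1, 3)[:, 2].sum() == pytest.approx(-400.0)
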