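"""Sparse linear statics: assembly, loading, solution, post-processing.

Constant-strain tetrahedra (the standard linear 4-node element), two-node
trusses, and scalar joint springs are assembled into a symmetric stiffness
matrix solved by sparse LU.  The follower preload is applied as a uniformly
distributed compressive load on the loaded surface along the segment axis;
pure moments are applied as a self-equilibrated force couple distributed
over the loaded surface.  Facet springs are compression-only: after a first
solve, springs found in tension are deactivated and the case is re-solved
once (a single fixed-point update).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

DIRECTIONS = ("flexion", "extension", "left_bending", "right_bending",
              "left_rotation", "right_rotation")

#: moment axis (right-hand rule) for each direction in the model frame
#: (+x right, +y anterior, +z cranial)
MOMENT_AXES = {
    "flexion": np.array([-1.0, 0.0, 0.0]),   # tilts the top anteriorly
    "extension": np.array([1.0, 0.0, 0.0]),
    "right_bending": np.array([0.0, 1.0, 0.0]),
    "left_bending": np.array([0.0, -1.0, 0.0]),
    "left_rotation": np.array([0.0, 0.0, 1.0]),
    "right_rotation": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class LoadCase:
    direction: str = "flexion"
    follower_load: float = 400.0    # N
    moment: float = 10.0            # N*m

    def validate(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.follower_load < 0 or self.moment < 0:
            raise ValueError("load magnitudes must be >= 0")


def isotropic_C(young: float, poisson: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (Voigt, engineering shear)."""
    e, nu = young, poisson
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def tet_b_matrices(nodes: np.ndarray, tets: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices (n_tet, 6, 12) and volumes."""
    p = nodes[tets]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    v3 = p[:, 3] - p[:, 0]
    det = np.einsum("ij,ij->i", v1, np.cross(v2, v3))
    vol = det / 6.0
    if (vol <= 0).any():
        raise ValueError("negative-volume tetrahedron in assembly")
    # gradients of the four shape functions
    minv = np.linalg.inv(np.stack([v1, v2, v3], axis=1))
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = np.transpose(minv, (0, 2, 1))
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    B = np.zeros((len(tets), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def assemble_stiffness(fem) -> csc_matrix:
    """Global stiffness of tets + trusses + active springs."""
    mesh = fem.mesh
    n_dof = 3 * len(mesh.nodes)
    B, vol = tet_b_matrices(mesh.nodes, mesh.tets)
    n_tet = len(mesh.tets)
    ke = np.empty((n_tet, 12, 12))
    # group tets by material to batch the C-matrix product
    mats = np.column_stack([mesh.young, mesh.poisson])
    for row in np.unique(mats, axis=0):
        sel = np.all(mats == row, axis=1)
        C = isotropic_C(row[0], row[1])
        CB = np.einsum("ij,njk->nik", C, B[sel])
        ke[sel] = np.einsum("nji,njk->nik", B[sel], CB) \
            * vol[sel][:, None, None]
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(n_tet, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    data = ke.ravel()

    extra_rows, extra_cols, extra_data = [rows], [cols], [data]
    for t in fem.trusses:
        if not getattr(t, "active", True):
            continue
        if getattr(t, "embedded", False):
            k_loc, d = _embedded_truss_matrix(t)
        else:
            k_loc, d = _truss_matrix(mesh.nodes, t.n1, t.n2,
                                     t.young * t.area)
        r, c = np.meshgrid(d, d, indexing="ij")
        extra_rows.append(r.ravel())
        extra_cols.append(c.ravel())
        extra_data.append(k_loc.ravel())
    for s in fem.springs:
        k_loc, d = _spring_matrix(s)
        if k_loc is None:
            continue
        r, c = np.meshgrid(d, d, indexing="ij")
        extra_rows.append(r.ravel())
        extra_cols.append(c.ravel())
        extra_data.append(k_loc.ravel())

    K = coo_matrix((np.concatenate(extra_data),
                    (np.concatenate(extra_rows),
                     np.concatenate(extra_cols))),
                   shape=(n_dof, n_dof)).tocsc()
    return K


def _truss_matrix(nodes: np.ndarray, n1: int, n2: int,
                  ea: float) -> tuple[np.ndarray, np.ndarray]:
    vec = nodes[n2] - nodes[n1]
    L = np.linalg.norm(vec)
    if L < 1e-9:
        raise ValueError("zero-length truss")
    d = vec / L
    k = ea / L
    outer = np.outer(d, d)
    k_loc = np.block([[outer, -outer], [-outer, outer]]) * k
    dofs = np.concatenate([3 * n1 + np.arange(3), 3 * n2 + np.arange(3)])
    return k_loc, dofs


def _embedded_truss_matrix(t) -> tuple[np.ndarray, np.ndarray]:
    """Stiffness of a truss embedded at exact points via trilinear weights.

    Length and direction come from the geometric endpoints, so the axial
    stiffness EA/L is mesh-independent; the rank-one block is spread over
    the supporting nodes with signed interpolation coefficients.
    """
    vec = t.p2 - t.p1
    L = np.linalg.norm(vec)
    if L < 1e-9:
        raise ValueError("zero-length truss")
    d = vec / L
    k3 = (t.young * t.area / L) * np.outer(d, d)
    coeffs = np.concatenate([-t.w1, t.w2])
    supports = np.concatenate([t.support1, t.support2])
    n = len(supports)
    k_loc = np.empty((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            k_loc[3 * i:3 * i + 3, 3 * j:3 * j + 3] = \
                coeffs[i] * coeffs[j] * k3
    dofs = (3 * supports[:, None] + np.arange(3)).ravel()
    return k_loc, dofs


def _spring_matrix(s):
    """3x3 facet connector block.

    Normal direction: contact stiffness, gated (compression only).
    Horizontal in-plane tangent: shear stiffness of the intact
    articulation (curvature interlock + capsule); carried regardless of
    gating while the cartilage is present.
    Vertical in-plane tangent: free -- the physiological articular glide.
    """
    d = s.direction / np.linalg.norm(s.direction)
    k3 = np.zeros((3, 3))
    if s.active:
        k3 += s.stiffness * np.outer(d, d)
    k_t = getattr(s, "tangential_stiffness", 0.0)
    if k_t > 0.0:
        h = np.cross([0.0, 0.0, 1.0], d)
        norm = np.linalg.norm(h)
        if norm > 1e-9:
            h /= norm
            k3 += k_t * np.outer(h, h)
    if not k3.any():
        return None, None
    if getattr(s, "embedded", False):
        coeffs = np.concatenate([-s.w1, s.w2])
        supports = np.concatenate([s.support1, s.support2])
        n = len(supports)
        k_loc = np.empty((3 * n, 3 * n))
        for i in range(n):
            for j in range(n):
                k_loc[3 * i:3 * i + 3, 3 * j:3 * j + 3] = \
                    coeffs[i] * coeffs[j] * k3
        dofs = (3 * supports[:, None] + np.arange(3)).ravel()
        return k_loc, dofs
    k_loc = np.block([[k3, -k3], [-k3, k3]])
    dofs = np.concatenate([3 * s.n1 + np.arange(3), 3 * s.n2 + np.arange(3)])
    return k_loc, dofs


def build_load_vector(fem, load: LoadCase) -> np.ndarray:
    """Follower preload plus a pure-moment force couple on the load nodes."""
    load.validate()
    mesh = fem.mesh
    f = np.zeros(3 * len(mesh.nodes))
    nodes = fem.load_nodes
    if load.follower_load > 0:
        # compressive load along the segment axis (-z in the neutral frame)
        per_node = load.follower_load / len(nodes)
        f[3 * nodes + 2] -= per_node
    if load.moment > 0:
        axis = MOMENT_AXES[load.direction]
        centroid = mesh.nodes[nodes].mean(axis=0)
        r = mesh.nodes[nodes] - centroid
        # f_i = alpha (axis x r_i): a pure couple with zero net force
        arms = np.cross(axis[None, :], r)
        denom = float(np.einsum("ij,ij->", np.cross(r, arms), axis[None, :]))
        if denom < 1e-9:
            raise ValueError("load surface cannot carry the moment")
        alpha = load.moment * 1000.0 / denom     # N*m -> N*mm
        forces = alpha * arms
        f[(3 * nodes)[:, None] + np.arange(3)] += forces
    return f


def assemble_and_solve(fem, load: LoadCase,
                        lu=None, compression_only: bool = True,
                        ) -> tuple[np.ndarray, list]:
    """Solve one load case, with one compression-only facet update.

    Returns displacements and the list of springs deactivated for this
    case.  ``lu`` may carry a pre-factorized all-springs-active operator.
    """
    K = None
    if lu is None:
        K = assemble_stiffness(fem)
        lu = factorize(fem, K)
    f = build_load_vector(fem, load)
    u = _solve_fixed(fem, lu, f)
    deactivated = []
    if compression_only:
        springs, fibers = _released_elements(fem, u)
        if springs or fibers:
            for el in springs + fibers:
                el.active = False
            lu2 = factorize(fem, assemble_stiffness(fem))
            u = _solve_fixed(fem, lu2, f)
            for el in springs + fibers:
                el.active = True
            deactivated = springs + fibers
    return u, deactivated


def _tension_springs(fem, u: np.ndarray) -> list:
    out = []
    ur = u.reshape(-1, 3)
    for s in fem.springs:
        if not s.active:
            continue
        d = s.direction / np.linalg.norm(s.direction)
        if getattr(s, "embedded", False):
            u1 = (s.w1[:, None] * ur[s.support1]).sum(axis=0)
            u2 = (s.w2[:, None] * ur[s.support2]).sum(axis=0)
            du = u2 - u1
        else:
            du = ur[s.n2] - ur[s.n1]
        # positive elongation along the joint normal = separation
        if float(du @ d) > 0:
            out.append(s)
    return out


def _truss_elongation(fem, t, u: np.ndarray) -> float:
    ur = u.reshape(-1, 3)
    if getattr(t, "embedded", False):
        u1 = (t.w1[:, None] * ur[t.support1]).sum(axis=0)
        u2 = (t.w2[:, None] * ur[t.support2]).sum(axis=0)
        vec = t.p2 - t.p1
    else:
        u1, u2 = ur[t.n1], ur[t.n2]
        vec = fem.mesh.nodes[t.n2] - fem.mesh.nodes[t.n1]
    d = vec / np.linalg.norm(vec)
    return float((u2 - u1) @ d)


def _released_elements(fem, u: np.ndarray) -> tuple[list, list]:
    """Springs separating along their contact normal and tension-only
    trusses found in compression under the current solution."""
    springs = _tension_springs(fem, u)
    fibers = [t for t in fem.trusses
              if getattr(t, "tension_only", False)
              and getattr(t, "active", True)
              and _truss_elongation(fem, t, u) < 0.0]
    return springs, fibers


class _FixedOperator:
    """LU of the stiffness with fixed dofs eliminated."""

    def __init__(self, lu, free, n_dof, K):
        self.lu = lu
        self.free = free
        self.n_dof = n_dof
        self.K = K


def factorize(fem, K: csc_matrix) -> _FixedOperator:
    n_dof = K.shape[0]
    fixed_dofs = (3 * fem.fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n_dof), fixed_dofs)
    Kff = K[np.ix_(free, free)]
    return _FixedOperator(splu(Kff.tocsc()), free, n_dof, K)


def _solve_fixed(fem, op: _FixedOperator, f: np.ndarray) -> np.ndarray:
    u = np.zeros(op.n_dof)
    u[op.free] = op.lu.solve(f[op.free])
    return u


def reaction_residual(fem, K: csc_matrix, u: np.ndarray,
                      f: np.ndarray) -> float:
    """Relative equilibrium residual: reactions must balance applied loads."""
    r = K @ u - f
    fixed_dofs = (3 * fem.fixed_nodes[:, None] + np.arange(3)).ravel()
    reactions = r[fixed_dofs]
    applied = f.reshape(-1, 3).sum(axis=0)
    total = reactions.reshape(-1, 3).sum(axis=0) + applied
    scale = max(np.abs(f).sum(), 1e-12)
    return float(np.linalg.norm(total) / scale)


def compute_von_mises(fem, u: np.ndarray) -> np.ndarray:
    """Constant von Mises stress per tetrahedron (MPa)."""
    mesh = fem.mesh
    B, _ = tet_b_matrices(mesh.nodes, mesh.tets)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(len(mesh.tets), 12)
    strain = np.einsum("nij,nj->ni", B, ue)
    stress = np.empty_like(strain)
    mats = np.column_stack([mesh.young, mesh.poisson])
    for row in np.unique(mats, axis=0):
        sel = np.all(mats == row, axis=1)
        C = isotropic_C(row[0], row[1])
        stress[sel] = strain[sel] @ C.T
    sx, sy, sz, txy, tyz, tzx = stress.T
    vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                 + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))
    return vm


def region_max_von_mises(fem, vm: np.ndarray, region_names: list[str],
                         nodal_average: bool = True) -> dict[str, float]:
    """Per-region maximum von Mises stress.

    With ``nodal_average`` (default) the element stresses are first
    projected to nodes by volume-weighted averaging within the region --
    the standard smoothing for constant-strain tetrahedra, which removes
    single-element corner artifacts of the lattice discretisation.
    """
    out = {}
    vols = fem.mesh.tet_volumes
    for name in region_names:
        sel = fem.mesh.region_of_tet == name
        if not sel.any():
            out[name] = 0.0
            continue
        if not nodal_average:
            out[name] = float(vm[sel].max())
            continue
        tets, v, w = fem.mesh.tets[sel], vm[sel], vols[sel]
        num = np.zeros(len(fem.mesh.nodes))
        den = np.zeros(len(fem.mesh.nodes))
        for c in range(4):
            np.add.at(num, tets[:, c], v * w)
            np.add.at(den, tets[:, c], w)
        used = den > 0
        out[name] = float((num[used] / den[used]).max())
    return out


def fit_rigid_rotation(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Least-squares rotation of a point cloud (Kabsch)."""
    if len(x0) < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    c0, c1 = x0.mean(axis=0), x1.mean(axis=0)
    H = (x0 - c0).T @ (x1 - c1)
    U, svals, Vt = np.linalg.svd(H)
    if svals[1] < 1e-9:
        raise ValueError("degenerate (collinear) point cloud")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    return Vt.T @ D @ U.T


def compute_rom(fem, u: np.ndarray, level: str = "L4L5") -> float:
    """Relative vertebral rotation in degrees.

    A rigid rotation is fitted to each vertebra's displaced body nodes; the
    reported range of motion is the total angle of the relative rotation of
    the cranial vertebra with respect to the caudal one.
    """
    cranial, caudal = level[:2], level[2:]
    ur = u.reshape(-1, 3)
    angles = {}
    for vert in (cranial, caudal):
        ids = fem.mesh.node_sets[f"{vert}_body"]
        x0 = fem.mesh.nodes[ids]
        x1 = x0 + ur[ids]
        angles[vert] = fit_rigid_rotation(x0, x1)
    r_rel = angles[cranial] @ angles[caudal].T
    cos_t = np.clip((np.trace(r_rel) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_t)))
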