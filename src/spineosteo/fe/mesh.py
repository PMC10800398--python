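"""Lattice tetrahedral meshing of the phantom.

The phantom's solid regions are layered along the cranio-caudal axis, so a
rectilinear lattice -- uniform in x/y, graded in z to land exactly on the
disc, endplate and body interfaces -- resolves the 1 mm endplates with a
dedicated element layer while keeping the vertebral bodies coarse.  Each
occupied cell is split into six tetrahedra with the Freudenthal (Kuhn)
decomposition, which is conforming across neighbouring cells, and every
region interface shares lattice nodes by construction.

Cells are classified on a 2x2x2 sub-grid: boundary cells join the mesh
with their modulus scaled by occupancy (partial-volume homogenisation),
which removes the first-order staircase error of center-only labelling.
The thin cortical wall (1 mm) is below the lateral lattice resolution, so
a fixed-thickness lateral band of each vertebral body is assigned the
cortical material instead; this overweights cortical bone but leaves the
segment kinematics essentially unchanged because the vertebrae act as
near-rigid bodies relative to the discs and ligaments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..anatomy import AnatomyModel
from ..convex import ConvexSolid
from .materials import MATERIALS, material_for_region

#: thickness of the homogenised cortical band on the lattice, mm (fixed
#: so the shell stiffness does not change with mesh refinement)
CORTICAL_BAND_MM = 3.0

#: labelling priority: thin/interior structures win over enclosing ones
_PRIORITY = (
    "nucleus", "annulus", "endplate", "cancellous", "cortical",
    "posterior_elements",
)


def _region_rank(name: str) -> int:
    for i, key in enumerate(_PRIORITY):
        if key in name:
            return i
    return len(_PRIORITY)


# Freudenthal 6-tet decomposition of the unit cube; corners indexed
# c = 4*i + 2*j + k for offsets (i, j, k) along (x, y, z)
_FREUDENTHAL = np.array([
    [0, 4, 6, 7],
    [0, 6, 2, 7],
    [0, 2, 3, 7],
    [0, 3, 1, 7],
    [0, 1, 5, 7],
    [0, 5, 4, 7],
])


def graded_levels(breaks: list[float], target: float) -> np.ndarray:
    """Monotone level set containing all breakpoints, spacing <= target."""
    breaks = np.unique(np.round(np.asarray(breaks, float), 9))
    levels = [breaks[0]]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((hi - lo) / target - 1e-9)))
        levels.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(levels)


def lattice_tets(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
                 cell_mask: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tets for the masked cells of a rectilinear lattice.

    Returns ``(nodes, tets, cell_index_of_tet, used_grid_ids)`` where tets
    reference rows of ``nodes``, every retained cell contributes six
    positive-volume tetrahedra sharing lattice nodes with its neighbours,
    and ``used_grid_ids`` maps compact node ids back to the full grid.
    """
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    if cell_mask.shape != (nx, ny, nz):
        raise ValueError("cell_mask shape mismatch")
    ci, cj, ck = np.nonzero(cell_mask)
    if len(ci) == 0:
        raise ValueError("no occupied cells")

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    corners = np.empty((len(ci), 8), dtype=np.int64)
    for c in range(8):
        di, dj, dk = c >> 2 & 1, c >> 1 & 1, c & 1
        corners[:, c] = node_id(ci + di, cj + dj, ck + dk)
    tets_global = corners[:, _FREUDENTHAL].reshape(-1, 4)
    cell_of_tet = np.repeat(np.arange(len(ci)), len(_FREUDENTHAL))

    used, inverse = np.unique(tets_global, return_inverse=True)
    tets = inverse.reshape(-1, 4)
    gi, rem = np.divmod(used, nz + 1)
    gi, gj = np.divmod(gi, ny + 1)
    nodes = np.column_stack([xs[gi], ys[gj], zs[rem]])
    return nodes, tets, cell_of_tet, used


@dataclass
class LatticeMesh:
    """Labeled tet mesh of the phantom plus lattice bookkeeping."""

    nodes: np.ndarray
    tets: np.ndarray
    region_of_tet: np.ndarray          # region-name strings
    young: np.ndarray
    poisson: np.ndarray
    spacing: float
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    # lattice levels and the map from grid node index to compact node id
    # (-1 where the grid node is unused); kept so attachment points can be
    # embedded with trilinear weights instead of snapping to nodes
    xs: np.ndarray | None = None
    ys: np.ndarray | None = None
    zs: np.ndarray | None = None
    grid_node_map: np.ndarray | None = None

    @property
    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.abs(np.einsum(
            "ij,ij->i", p[:, 1] - p[:, 0],
            np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))) / 6.0

    #: per-joint node remaps created by the facet split (cranial side)
    split_remaps: dict | None = None

    def anchor_at(self, point: np.ndarray):
        """Trilinear embedding of a point in its containing lattice cell.

        Returns ``(node_ids, weights)`` over the cell's corners, or
        ``None`` when the point falls outside the grid or its cell has
        unused corners (caller falls back to nearest-node snapping).
        Anchors are resolved before facet-joint node splitting, so they
        must not be used across an articular gap.
        """
        if self.grid_node_map is None:
            return None
        point = np.asarray(point, float)
        i = int(np.searchsorted(self.xs, point[0], side="right") - 1)
        j = int(np.searchsorted(self.ys, point[1], side="right") - 1)
        k = int(np.searchsorted(self.zs, point[2], side="right") - 1)
        if not (0 <= i < len(self.xs) - 1 and 0 <= j < len(self.ys) - 1
                and 0 <= k < len(self.zs) - 1):
            return None
        fx = (point[0] - self.xs[i]) / (self.xs[i + 1] - self.xs[i])
        fy = (point[1] - self.ys[j]) / (self.ys[j + 1] - self.ys[j])
        fz = (point[2] - self.zs[k]) / (self.zs[k + 1] - self.zs[k])
        ny1, nz1 = len(self.ys), len(self.zs)
        ids, weights = [], []
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    gid = ((i + di) * ny1 + (j + dj)) * nz1 + (k + dk)
                    nid = self.grid_node_map[gid]
                    if nid < 0:
                        return None
                    ids.append(nid)
                    weights.append(wx * wy * wz)
        return np.asarray(ids), np.asarray(weights)


def tetrahedralize(model: AnatomyModel, target_edge_mm: float = 3.5,
                   ) -> LatticeMesh:
    """Conforming labeled tet mesh of all solid regions of the phantom.

    Facet cartilage is not meshed volumetrically (it is thinner than any
    practical lattice spacing); the articulation is represented by joint
    springs added by the model builder.
    """
    if abs(model.params.lordosis_angle_per_level) > 1e-9:
        raise ValueError("the lattice mesher requires the neutral "
                         "(zero-lordosis) phantom")
    p = model.params
    d, h, te = p.disc_height, p.vertebral_body_height, p.endplate_thickness
    body_breaks = []
    for z0 in (-d / 2 - h, d / 2, d / 2 + h + d):          # bodies
        body_breaks += [z0, z0 + h]
    zs = graded_levels(body_breaks, target_edge_mm)
    # disc cores drive the segment's bending stiffness: guarantee at least
    # six element layers through each core regardless of the lateral target
    core = d - 2 * te
    core_dz = min(target_edge_mm, core / 6.0)
    for z0 in (-d / 2, d / 2 + h):                          # discs
        disc_levels = graded_levels(
            [z0, z0 + te, z0 + d - te, z0 + d], core_dz)
        zs = np.unique(np.concatenate([zs, disc_levels]))

    solid_regions = {name: region for name, region in model.regions.items()
                     if not name.startswith("facet_cartilage")}
    verts = np.vstack([part.vertices
                       for region in solid_regions.values()
                       for part in region.pos])
    lo, hi = verts.min(axis=0) - 1e-6, verts.max(axis=0) + 1e-6
    xs = np.arange(lo[0], hi[0] + target_edge_mm, target_edge_mm)
    ys = np.arange(lo[1], hi[1] + target_edge_mm, target_edge_mm)

    cx = (xs[:-1] + xs[1:]) / 2.0
    cy = (ys[:-1] + ys[1:]) / 2.0
    cz = (zs[:-1] + zs[1:]) / 2.0
    dz = (zs[1:] - zs[:-1])
    shape = (len(cx), len(cy), len(cz))

    # partial-volume classification: each cell is probed at a 2x2x2
    # sub-grid; boundary cells enter the mesh with their modulus scaled by
    # occupancy, which removes the first-order staircase error of
    # center-only labelling
    names = sorted(solid_regions, key=_region_rank)
    counts = np.zeros((len(names), np.prod(shape)), dtype=np.int16)
    offsets = np.array([[sx, sy, sz]
                        for sx in (-0.25, 0.25)
                        for sy in (-0.25, 0.25)
                        for sz in (-0.25, 0.25)])
    for off in offsets:
        gx = cx + off[0] * target_edge_mm
        gy = cy + off[1] * target_edge_mm
        pts = np.stack(np.meshgrid(gx, gy, cz, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        pts[:, 2] += off[2] * np.tile(dz, len(cx) * len(cy))
        sub_label = np.full(len(pts), -1, dtype=np.int64)
        for idx in range(len(names) - 1, -1, -1):
            sub_label[solid_regions[names[idx]].contains(pts)] = idx
        # cortical override at fixed physical band thickness
        for vert in ("L3", "L4", "L5"):
            outer = model.regions[f"{vert}_cortical"].pos[0]
            inset = ConvexSolid(outer.A, outer.b - CORTICAL_BAND_MM)
            in_band = outer.contains(pts) & ~inset.contains(pts)
            body_idx = (names.index(f"{vert}_cortical"),
                        names.index(f"{vert}_cancellous"))
            sub_label[in_band & np.isin(sub_label, body_idx)] = \
                names.index(f"{vert}_cortical")
        hit = sub_label >= 0
        counts[sub_label[hit], np.flatnonzero(hit)] += 1

    occupancy = counts.sum(axis=0) / len(offsets)
    label = np.where(occupancy > 0, counts.argmax(axis=0), -1)
    # a partial cell whose sub-points touch the articular processes of two
    # different vertebrae straddles the sub-cell joint gap and would
    # bridge the articulation; such cells are re-classified by their
    # center point and keep only their own side's volume fraction
    post_idx = {nm: i for i, nm in enumerate(names)
                if nm.endswith("posterior_elements")}
    straddle = np.zeros(len(label), dtype=bool)
    for a, b in (("L3", "L4"), ("L4", "L5")):
        straddle |= ((counts[post_idx[f"{a}_posterior_elements"]] > 0)
                     & (counts[post_idx[f"{b}_posterior_elements"]] > 0))
    if straddle.any():
        centers_flat = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"),
                                axis=-1).reshape(-1, 3)
        cells = np.flatnonzero(straddle)
        center_label = np.full(len(cells), -1, dtype=np.int64)
        for nm, idx in post_idx.items():
            inside = solid_regions[nm].contains(centers_flat[cells])
            center_label[inside] = idx
        label[cells] = center_label
        own = np.where(center_label >= 0,
                       counts[center_label, cells] / len(offsets), 0.0)
        occupancy[cells] = own
    label3 = label.reshape(shape)
    name_arr = np.array(names + ["_none_"])

    mask = label3 >= 0
    nodes, tets, cell_of_tet, used = lattice_tets(xs, ys, zs, mask)
    grid_map = -np.ones(len(xs) * len(ys) * len(zs), dtype=np.int64)
    grid_map[used] = np.arange(len(used))
    cell_labels = label3[mask]
    cell_occupancy = occupancy.reshape(shape)[mask]
    region_of_tet = name_arr[cell_labels[cell_of_tet]]

    young = np.empty(len(tets))
    poisson = np.empty(len(tets))
    for name in np.unique(region_of_tet):
        card = material_for_region(name)
        sel = region_of_tet == name
        young[sel] = card.young_modulus
        poisson[sel] = card.poisson_ratio
    young *= cell_occupancy[cell_of_tet]

    mesh = LatticeMesh(nodes=nodes, tets=tets, region_of_tet=region_of_tet,
                       young=young, poisson=poisson, spacing=target_edge_mm,
                       xs=xs, ys=ys, zs=zs, grid_node_map=grid_map)
    _split_facet_joints(mesh)
    _build_node_sets(mesh, model)
    return mesh


def _split_facet_joints(mesh: LatticeMesh) -> None:
    """Duplicate lattice nodes welded across a facet joint.

    The articular gap (cartilage + joint space, ~1 mm) is below the lattice
    spacing, so the two articular processes would otherwise share nodes and
    fuse rigidly.  Nodes referenced by the posterior elements of both
    vertebrae of a joint are duplicated; the cranial vertebra's tets take
    the copies, leaving load transfer across the joint to the springs.
    """
    for cranial, caudal in (("L3", "L4"), ("L4", "L5")):
        sel_c = mesh.region_of_tet == f"{cranial}_posterior_elements"
        sel_d = mesh.region_of_tet == f"{caudal}_posterior_elements"
        shared = np.intersect1d(np.unique(mesh.tets[sel_c]),
                                np.unique(mesh.tets[sel_d]))
        if len(shared) == 0:
            continue
        n0 = len(mesh.nodes)
        mesh.nodes = np.vstack([mesh.nodes, mesh.nodes[shared]])
        remap = np.arange(n0 + len(shared))
        remap[shared] = n0 + np.arange(len(shared))
        mesh.tets[sel_c] = remap[mesh.tets[sel_c]]
        if mesh.split_remaps is None:
            mesh.split_remaps = {}
        mesh.split_remaps[cranial] = remap



def _build_node_sets(mesh: LatticeMesh, model: AnatomyModel) -> None:
    """Fixed (L5 inferior surface) and loaded (L3 superior surface) nodes."""
    p = model.params
    d, h = p.disc_height, p.vertebral_body_height
    z_bottom = -d / 2.0 - h
    z_top = d / 2.0 + 2.0 * h + d
    tol = 1e-6
    node_region = _nodes_of_regions(mesh)
    bottom = np.flatnonzero(np.abs(mesh.nodes[:, 2] - z_bottom) < tol)
    top = np.flatnonzero(np.abs(mesh.nodes[:, 2] - z_top) < tol)
    l5 = node_region.get("L5", np.empty(0, np.int64))
    l3 = node_region.get("L3", np.empty(0, np.int64))
    fixed = np.intersect1d(bottom, l5)
    load = np.intersect1d(top, l3)
    if len(fixed) == 0 or len(load) == 0:
        raise ValueError("empty fixed or load node set")
    mesh.node_sets["fixed"] = fixed
    mesh.node_sets["load"] = load
    for vert in ("L3", "L4", "L5"):
        mesh.node_sets[f"{vert}_body"] = node_region[vert]


def _nodes_of_regions(mesh: LatticeMesh) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for vert in ("L3", "L4", "L5"):
        sel = np.isin(mesh.region_of_tet,
                      [f"{vert}_cortical", f"{vert}_cancellous"])
        out[vert] = np.unique(mesh.tets[sel])
    return out


def box_fe_model(lx: float, ly: float, lz: float,
                 nx: int, ny: int, nz: int,
                 young: float, poisson: float) -> LatticeMesh:
    """Structured tet mesh of a solid box (analytic verification problems)."""
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    mask = np.ones((nx, ny, nz), dtype=bool)
    nodes, tets, _, _ = lattice_tets(xs, ys, zs, mask)
    n = len(tets)
    mesh = LatticeMesh(nodes=nodes, tets=tets,
                       region_of_tet=np.full(n, "box"),
                       young=np.full(n, float(young)),
                       poisson=np.full(n, float(poisson)),
                       spacing=min(lx / nx, ly / ny, lz / nz))
    tol = 1e-9
    mesh.node_sets["fixed"] = np.flatnonzero(np.abs(nodes[:, 2]) < tol)
    mesh.node_sets["load"] = np.flatnonzero(np.abs(nodes[:, 2] - lz) < tol)
    return mesh
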