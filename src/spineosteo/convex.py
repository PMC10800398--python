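"""Exact convex-solid geometry engine.

Every solid in the synthetic phantom is an extrusion of a convex polygon,
i.e. an intersection of half-spaces ``{x : A x <= b}``.  Working in
half-space form makes the Boolean operations the pipeline needs -- volume of
an intersection with a trephine cylinder, point containment, difference
against a convex tool -- exact up to the polygonal discretisation of curved
cross-sections, with no dependence on a mesh-Boolean backend.

Anatomical regions that are not convex (cortical shells, the annulus around
the nucleus) are represented as signed unions of convex parts
(:class:`RegionSolid`), which keeps all volume arithmetic closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

_EMPTY_RADIUS = 1e-9


def superellipse_polygon(a: float, b: float, exponent: float = 2.5,
                         n: int = 64) -> np.ndarray:
    """Counter-clockwise vertex loop of ``|x/a|^p + |y/b|^p = 1``.

    The vertex count must be a multiple of 4 so that vertices land exactly
    on both symmetry axes (the mid-sagittal measurements rely on this).
    Convex for ``exponent >= 1``.
    """
    if n % 4:
        raise ValueError("vertex count must be a multiple of 4")
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    c, s = np.cos(theta), np.sin(theta)
    p = 2.0 / exponent
    x = a * np.sign(c) * np.abs(c) ** p
    y = b * np.sign(s) * np.abs(s) ** p
    return np.column_stack([x, y])


def rectangle_polygon(width: float, height: float,
                      center=(0.0, 0.0)) -> np.ndarray:
    w, h = width / 2.0, height / 2.0
    cx, cy = center
    return np.array([[cx - w, cy - h], [cx + w, cy - h],
                     [cx + w, cy + h], [cx - w, cy + h]])


def polygon_halfspaces(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outward edge half-spaces (unit normals) of a CCW convex polygon."""
    edges = np.roll(poly, -1, axis=0) - poly
    normals = np.column_stack([edges[:, 1], -edges[:, 0]])
    lengths = np.linalg.norm(normals, axis=1)
    if np.any(lengths < 1e-12):
        raise ValueError("degenerate polygon edge")
    normals /= lengths[:, None]
    offsets = np.einsum("ij,ij->i", normals, poly)
    return normals, offsets


def offset_polygon_inward(poly: np.ndarray, distance: float) -> np.ndarray:
    """Inward offset of a convex polygon by moving each edge line inward."""
    normals, offsets = polygon_halfspaces(poly)
    offsets = offsets - distance
    n = len(poly)
    verts = np.empty_like(poly)
    for i in range(n):
        j = (i - 1) % n
        mat = np.array([normals[j], normals[i]])
        rhs = np.array([offsets[j], offsets[i]])
        verts[i] = np.linalg.solve(mat, rhs)
    area = 0.5 * np.sum(verts[:, 0] * np.roll(verts[:, 1], -1)
                        - np.roll(verts[:, 0], -1) * verts[:, 1])
    if area <= 0 or (verts @ normals.T > offsets + 1e-9).any():
        raise ValueError("inward offset collapses polygon")
    return verts


def _apply_transform(points: np.ndarray, transform: np.ndarray) -> np.ndarray:
    return points @ transform[:3, :3].T + transform[:3, 3]


class ConvexSolid:
    """A bounded convex solid ``{x : A x <= b}`` with unit row normals."""

    def __init__(self, A: np.ndarray, b: np.ndarray, name: str = ""):
        A = np.asarray(A, dtype=float)
        b = np.asarray(b, dtype=float)
        norms = np.linalg.norm(A, axis=1)
        self.A = A / norms[:, None]
        self.b = b / norms
        self.name = name
        self._vertices: np.ndarray | None = None
        self._interior: np.ndarray | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_extrusion(cls, polygon: np.ndarray, z0: float, z1: float,
                       transform: np.ndarray | None = None,
                       name: str = "") -> "ConvexSolid":
        """Extrude a CCW convex polygon along local +z, then rigidly place it."""
        if z1 <= z0:
            raise ValueError(f"empty extrusion range for {name!r}")
        normals2d, offsets2d = polygon_halfspaces(np.asarray(polygon, float))
        n = len(normals2d)
        A = np.zeros((n + 2, 3))
        A[:n, :2] = normals2d
        A[n] = [0.0, 0.0, -1.0]
        A[n + 1] = [0.0, 0.0, 1.0]
        b = np.concatenate([offsets2d, [-z0, z1]])
        solid = cls(A, b, name=name)
        if transform is not None:
            solid = solid.transformed(transform)
        solid._cross_section = np.asarray(polygon, float)
        solid._z_range = (z0, z1)
        solid._transform = (np.eye(4) if transform is None
                            else np.asarray(transform, float))
        return solid

    def transformed(self, transform: np.ndarray) -> "ConvexSolid":
        R = np.asarray(transform, float)[:3, :3]
        t = np.asarray(transform, float)[:3, 3]
        A = self.A @ R.T
        b = self.b + A @ t
        out = ConvexSolid(A, b, name=self.name)
        for attr in ("_cross_section", "_z_range"):
            if hasattr(self, attr):
                setattr(out, attr, getattr(self, attr))
        if hasattr(self, "_transform"):
            out._transform = np.asarray(transform, float) @ self._transform
        return out

    def intersect(self, other: "ConvexSolid", name: str = "") -> "ConvexSolid":
        return ConvexSolid(np.vstack([self.A, other.A]),
                           np.concatenate([self.b, other.b]),
                           name=name or f"{self.name}&{other.name}")

    # -- queries ----------------------------------------------------------

    def chebyshev_center(self) -> tuple[np.ndarray | None, float]:
        """Center and radius of the largest inscribed ball (None if empty)."""
        n = self.A.shape[1]
        c = np.zeros(n + 1)
        c[-1] = -1.0
        A_ub = np.hstack([self.A, np.ones((len(self.b), 1))])
        res = linprog(c, A_ub=A_ub, b_ub=self.b,
                      bounds=[(None, None)] * n + [(0, None)],
                      method="highs")
        if not res.success or res.x[-1] <= _EMPTY_RADIUS:
            return None, 0.0
        return res.x[:n], float(res.x[-1])

    @property
    def is_empty(self) -> bool:
        return self.vertices is None

    @property
    def vertices(self) -> np.ndarray | None:
        if self._vertices is None:
            center, radius = self.chebyshev_center()
            if center is None:
                self._vertices = None
                self._interior = None
                return None
            self._interior = center
            halfspaces = np.hstack([self.A, -self.b[:, None]])
            try:
                hs = HalfspaceIntersection(halfspaces, center)
            except QhullError:
                self._vertices = None
                return None
            self._vertices = hs.intersections
        return self._vertices

    @property
    def volume(self) -> float:
        verts = self.vertices
        if verts is None or len(verts) < 4:
            return 0.0
        try:
            return float(ConvexHull(verts).volume)
        except QhullError:
            return 0.0

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.all(points @ self.A.T <= self.b + tol, axis=1)

    def intersection_volume(self, other: "ConvexSolid") -> float:
        return self.intersect(other).volume

    # -- meshing ----------------------------------------------------------

    def to_mesh(self) -> trimesh.Trimesh:
        """Watertight surface mesh (outward-oriented convex hull)."""
        if hasattr(self, "_cross_section"):
            poly = _apply_transform(
                np.column_stack([self._cross_section,
                                 np.zeros(len(self._cross_section))]),
                self._transform)[:, :]
            return prism_mesh(self._cross_section, *self._z_range,
                              self._transform)
        verts = self.vertices
        if verts is None:
            raise ValueError(f"cannot mesh empty solid {self.name!r}")
        hull = ConvexHull(verts)
        mesh = trimesh.Trimesh(vertices=verts, faces=hull.simplices,
                               process=True)
        mesh.fix_normals()
        return mesh

    def difference_pieces(self, tool: "ConvexSolid") -> list["ConvexSolid"]:
        """``self - tool`` as disjoint convex pieces.

        Uses the half-space decomposition of the tool complement: the piece
        behind tool plane i is ``self & {a_i x >= b_i} & {a_j x <= b_j, j<i}``,
        which tiles ``self \\ tool`` without overlap.
        """
        pieces = []
        for i in range(len(tool.b)):
            A = np.vstack([self.A, -tool.A[i:i + 1], tool.A[:i]])
            b = np.concatenate([self.b, [-tool.b[i]], tool.b[:i]])
            piece = ConvexSolid(A, b, name=f"{self.name}-piece{i}")
            if piece.vertices is not None and piece.volume > 1e-9:
                pieces.append(piece)
        return pieces


@dataclass
class RegionSolid:
    """Anatomical region = union(pos parts) minus union(neg parts).

    Positive parts are mutually disjoint by construction; negative parts lie
    inside a positive part, so all volume arithmetic is additive.
    """

    name: str
    pos: list[ConvexSolid] = field(default_factory=list)
    neg: list[ConvexSolid] = field(default_factory=list)

    @property
    def volume(self) -> float:
        return (sum(p.volume for p in self.pos)
                - sum(n.volume for n in self.neg))

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        inside = np.zeros(len(points), dtype=bool)
        for p in self.pos:
            inside |= p.contains(points)
        for n in self.neg:
            inside &= ~n.contains(points, tol=-1e-9)
        return inside

    def intersection_volume(self, tool: ConvexSolid) -> float:
        bounds_reject = _bbox_disjoint(self, tool)
        if bounds_reject:
            return 0.0
        vol = sum(p.intersection_volume(tool) for p in self.pos)
        vol -= sum(n.intersection_volume(tool) for n in self.neg)
        return max(vol, 0.0)

    def to_mesh(self) -> trimesh.Trimesh:
        meshes = [p.to_mesh() for p in self.pos]
        for n in self.neg:
            m = n.to_mesh()
            m.invert()
            meshes.append(m)
        mesh = trimesh.util.concatenate(meshes)
        return mesh


def _bbox_disjoint(region: RegionSolid, tool: ConvexSolid) -> bool:
    tv = tool.vertices
    if tv is None:
        return True
    lo_t, hi_t = tv.min(axis=0), tv.max(axis=0)
    for p in region.pos:
        pv = p.vertices
        if pv is None:
            continue
        if np.all(pv.max(axis=0) >= lo_t - 1e-9) and \
           np.all(pv.min(axis=0) <= hi_t + 1e-9):
            return False
    return True


# -- structured meshes for extrusions ------------------------------------

def prism_mesh(polygon: np.ndarray, z0: float, z1: float,
               transform: np.ndarray | None = None) -> trimesh.Trimesh:
    """Watertight prism over a convex CCW polygon (fan caps, quad walls)."""
    poly = np.asarray(polygon, float)
    n = len(poly)
    bottom = np.column_stack([poly, np.full(n, z0)])
    top = np.column_stack([poly, np.full(n, z1)])
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(1, n - 1):  # caps: fan (valid for convex polygons)
        faces.append([0, i + 1, i])          # bottom, outward (-z)
        faces.append([n, n + i, n + i + 1])  # top, outward (+z)
    for i in range(n):  # side quads
        j = (i + 1) % n
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                           process=False)
    if transform is not None:
        mesh.apply_transform(transform)
    return mesh


def annular_prism_mesh(outer: np.ndarray, inner: np.ndarray,
                       z0: float, z1: float,
                       transform: np.ndarray | None = None) -> trimesh.Trimesh:
    """Watertight prism over an annular region (outer minus inner polygon).

    Both loops must have the same vertex count and compatible angular
    ordering; the caps are quad strips between matched vertices.
    """
    outer = np.asarray(outer, float)
    inner = np.asarray(inner, float)
    if len(outer) != len(inner):
        raise ValueError("outer and inner loops must have equal vertex count")
    n = len(outer)
    verts = np.vstack([
        np.column_stack([outer, np.full(n, z0)]),   # 0..n-1
        np.column_stack([inner, np.full(n, z0)]),   # n..2n-1
        np.column_stack([outer, np.full(n, z1)]),   # 2n..3n-1
        np.column_stack([inner, np.full(n, z1)]),   # 3n..4n-1
    ])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        # outer wall (outward)
        faces += [[i, j, 2 * n + j], [i, 2 * n + j, 2 * n + i]]
        # inner wall (faces the cavity)
        faces += [[n + i, 3 * n + j, n + j], [n + i, 3 * n + i, 3 * n + j]]
        # bottom annulus (normal -z)
        faces += [[i, n + j, j], [i, n + i, n + j]]
        # top annulus (normal +z)
        faces += [[2 * n + i, 2 * n + j, 3 * n + j],
                  [2 * n + i, 3 * n + j, 3 * n + i]]
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                           process=False)
    if transform is not None:
        mesh.apply_transform(transform)
    return mesh


def _ear_clip(points2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW polygon by ear clipping (indices)."""
    n = len(points2d)
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return ((points2d[a][0] - points2d[o][0])
                * (points2d[b][1] - points2d[o][1])
                - (points2d[a][1] - points2d[o][1])
                * (points2d[b][0] - points2d[o][0]))

    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        found = False
        for k in range(len(idx)):
            i0, i1, i2 = (idx[k - 1], idx[k], idx[(k + 1) % len(idx)])
            if cross(i0, i1, i2) <= 1e-12:
                continue
            # no other polygon vertex inside candidate ear
            ear = np.array([points2d[i0], points2d[i1], points2d[i2]])

            def cross2(u, v):
                return u[0] * v[1] - u[1] * v[0]

            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = points2d[j]
                d1 = cross2(ear[1] - ear[0], p - ear[0])
                d2 = cross2(ear[2] - ear[1], p - ear[1])
                d3 = cross2(ear[0] - ear[2], p - ear[2])
                if d1 > 1e-12 and d2 > 1e-12 and d3 > 1e-12:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                found = True
                break
        if not found:
            break
    if len(idx) == 3:
        tris.append(tuple(idx))
    return tris


def _cap_open_boundary(mesh: trimesh.Trimesh, normal: np.ndarray,
                       ) -> trimesh.Trimesh:
    """Close planar boundary loops left by a plane cut (loops assumed simple)."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return mesh
    # boundary edges directed as they appear in faces; cap winds opposite
    face_edges = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    bset = {tuple(e) for e in boundary}
    succ = {}
    for a, b in face_edges:
        if (min(a, b), max(a, b)) in bset:
            succ[b] = a
    loops = []
    visited = set()
    for start in list(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = succ.get(start)
        while cur is not None and cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = succ.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    if not loops:
        return mesh
    # project onto the cap plane and triangulate each loop
    normal = np.asarray(normal, float)
    basis = trimesh.geometry.plane_transform(origin=np.zeros(3),
                                             normal=normal)[:3, :3]
    new_faces = []
    verts = mesh.vertices
    for loop in loops:
        pts2d = (verts[loop] @ basis.T)[:, :2]
        area = 0.5 * np.sum(pts2d[:, 0] * np.roll(pts2d[:, 1], -1)
                            - np.roll(pts2d[:, 0], -1) * pts2d[:, 1])
        if area < 0:
            loop = loop[::-1]
            pts2d = pts2d[::-1]
        for i0, i1, i2 in _ear_clip(pts2d):
            new_faces.append([loop[i0], loop[i1], loop[i2]])
    if not new_faces:
        return mesh
    out = trimesh.Trimesh(vertices=verts,
                          faces=np.vstack([mesh.faces, new_faces]),
                          process=True)
    out.fix_normals()
    return out


def clip_mesh_by_convex(mesh: trimesh.Trimesh,
                        solid: ConvexSolid) -> trimesh.Trimesh | None:
    """Clip an arbitrary watertight mesh by a convex solid (plane by plane).

    This is the path used for user-supplied surface meshes; phantom regions
    go through the exact half-space arithmetic instead.  Cut cross-sections
    must be simple loops (no nested holes).
    """
    clipped = mesh
    for normal, offset in zip(solid.A, solid.b):
        origin = normal * offset
        clipped = trimesh.intersections.slice_mesh_plane(
            clipped, -normal, origin, cap=False)
        if clipped is None or len(clipped.faces) == 0:
            return None
        clipped.merge_vertices(merge_tex=True, merge_norm=True)
        clipped = _cap_open_boundary(clipped, -normal)
    return clipped
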