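"""Assembly of the segment model: trusses, joint springs, surgical variants.

The solid lattice mesh is augmented with

* one truss per ligament fascicle (seven groups, areas divided over the
  group's fascicles),
* two criss-crossing annulus fiber truss families at +-30 degrees to the
  disc plane on the annulus perimeter,
* a connector grid across each facet joint: compression-gated contact
  stiffness along the (cranially tilted) mean articular normal, always-on
  horizontal shear stiffness while the cartilage is present, and free
  vertical glide (k = E or G x tributary area / cartilage + gap).

Surgical variants are applied by element death (tets whose centroid lies in
the trephine barrel), removal of capsular fascicles ordered by distance to
the tool axis, removal of the right ligamentum flavum (interlaminar
variant), and stripping the articular shear of connectors inside the
cartilage-removal footprint (bone-on-bone contact persists wherever the
process itself survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix

from ..anatomy import AnatomyModel
from ..convex import ConvexSolid
from ..planner import TrephinePlan, plan_frame, plan_tools, trephine_axis
from .materials import FASCICLES_PER_LEVEL, MATERIALS
from .mesh import LatticeMesh, tetrahedralize

MAX_ATTACH_DISTANCE = 5.0  # mm; ligament landmark must be this close to a node


@dataclass
class Truss:
    """Two-node axial member; optionally embedded at exact points.

    When anchor data is present the element couples to the corner nodes
    of the lattice cells containing its geometric endpoints with
    trilinear weights, so its length, direction and lever arm do not
    depend on the mesh.  ``n1``/``n2`` always hold the dominant support
    node of each end (used for reporting and coarse bookkeeping).
    """

    n1: int
    n2: int
    young: float
    area: float
    group: str
    level: str
    side: str
    index: int = 0
    p1: np.ndarray | None = None
    p2: np.ndarray | None = None
    support1: np.ndarray | None = None
    w1: np.ndarray | None = None
    support2: np.ndarray | None = None
    w2: np.ndarray | None = None
    #: collagen fibers buckle under compression; gated per load case
    tension_only: bool = False
    active: bool = True

    @property
    def embedded(self) -> bool:
        return self.support1 is not None

    def all_nodes(self) -> list[int]:
        if self.embedded:
            return list(self.support1) + list(self.support2)
        return [self.n1, self.n2]


@dataclass
class JointSpring:
    """Facet articulation connector.

    The normal stiffness (cartilage layers + joint space in series, along
    the tilted mean contact normal) acts only in compression and is gated
    per load case.  The tangential stiffness (articular shear,
    G = E / 2(1+nu)) acts along the horizontal in-plane tangent while the
    cartilage is present; vertical glide is free.
    """

    n1: int                  # node on the caudal (SAP) side
    n2: int                  # node on the cranial (IAP) side
    stiffness: float         # N/mm along the joint normal
    direction: np.ndarray    # unit joint normal (SAP -> IAP side)
    sample_point: np.ndarray
    joint: str               # e.g. "L4L5_right"
    tangential_stiffness: float = 0.0
    active: bool = True
    # trilinear supports: distributing each contact end over its cell
    # removes the artificial stress spikes of point-wise attachment
    support1: np.ndarray | None = None
    w1: np.ndarray | None = None
    support2: np.ndarray | None = None
    w2: np.ndarray | None = None

    @property
    def embedded(self) -> bool:
        return self.support1 is not None

    def all_nodes(self) -> list[int]:
        if self.embedded:
            return list(self.support1) + list(self.support2)
        return [self.n1, self.n2]


@dataclass
class FEModel:
    mesh: LatticeMesh
    trusses: list[Truss]
    springs: list[JointSpring]
    fixed_nodes: np.ndarray
    load_nodes: np.ndarray
    variant_id: str = "M1"
    removal_report: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.mesh.nodes)
        if len(self.fixed_nodes) == 0 or len(self.load_nodes) == 0:
            raise ValueError("fixed and load node sets must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.load_nodes).size:
            raise ValueError("fixed and load node sets must be disjoint")
        if self.mesh.tets.max() >= n:
            raise ValueError("tet references an unknown node")
        if (self.mesh.tet_volumes <= 0).any():
            raise ValueError("non-positive tet volume")
        referenced = set(self.mesh.tets.ravel())
        for t in self.trusses:
            referenced.update(t.all_nodes())
        for s in self.springs:
            referenced.update(s.all_nodes())
        if len(referenced) != n:
            raise ValueError(f"{n - len(referenced)} orphan nodes")


@dataclass
class SurgicalVariant:
    """Recipe for one surgical model (intact or a trephine resection)."""

    id: str
    trephine: TrephinePlan | None = None
    capsular_fraction_removed: float = 0.0
    flavum_removed: str = "none"        # none | right
    cartilage_removal: str = "none"     # none|small|moderate|large|extensive

    def validate(self) -> None:
        if self.capsular_fraction_removed not in (0.0, 0.25, 0.5, 0.75):
            raise ValueError("capsular fraction must be 0, 1/4, 1/2 or 3/4")
        if self.flavum_removed not in ("none", "right"):
            raise ValueError("flavum_removed must be 'none' or 'right'")
        if self.cartilage_removal not in ("none", "small", "moderate",
                                          "large", "extensive"):
            raise ValueError("unknown cartilage_removal grade")
        if self.trephine is not None:
            self.trephine.validate()


VARIANTS: dict[str, SurgicalVariant] = {
    "M1": SurgicalVariant("M1"),
    "M2": SurgicalVariant(
        "M2", TrephinePlan(angle_deg=60, diameter_mm=8, attempts=1),
        capsular_fraction_removed=0.25, cartilage_removal="small"),
    "M3": SurgicalVariant(
        "M3", TrephinePlan(angle_deg=30, diameter_mm=8, attempts=1),
        flavum_removed="right", cartilage_removal="small"),
    "M4": SurgicalVariant(
        "M4", TrephinePlan(angle_deg=50, diameter_mm=8, attempts=1),
        capsular_fraction_removed=0.5, cartilage_removal="moderate"),
    "M5": SurgicalVariant(
        "M5", TrephinePlan(angle_deg=50, diameter_mm=8, attempts=2),
        capsular_fraction_removed=0.5, cartilage_removal="large"),
    "M6": SurgicalVariant(
        "M6", TrephinePlan(angle_deg=50, diameter_mm=9, attempts=1),
        capsular_fraction_removed=0.75, cartilage_removal="extensive"),
}


def _nearest_node(nodes: np.ndarray, point: np.ndarray,
                  candidates: np.ndarray | None = None) -> tuple[int, float]:
    pool = nodes if candidates is None else nodes[candidates]
    d = np.linalg.norm(pool - point, axis=1)
    k = int(np.argmin(d))
    idx = k if candidates is None else int(candidates[k])
    return idx, float(d[k])


def _resolve_end(mesh: LatticeMesh, point: np.ndarray,
                 label: str) -> tuple[int, np.ndarray, np.ndarray]:
    """Embed an attachment point, falling back to the nearest node.

    Returns ``(primary_node, support_ids, weights)``; the primary node is
    the max-weight support.  Raises if even the nearest node is farther
    than the attachment tolerance.
    """
    anchor = mesh.anchor_at(point)
    if anchor is not None:
        ids, weights = anchor
        return int(ids[np.argmax(weights)]), ids, weights
    nid, dist = _nearest_node(mesh.nodes, point)
    if dist > MAX_ATTACH_DISTANCE:
        raise ValueError(
            f"{label}: attachment {dist:.1f} mm from the nearest node "
            f"(> {MAX_ATTACH_DISTANCE} mm)")
    return nid, np.array([nid]), np.array([1.0])


def attach_ligaments(mesh: LatticeMesh, model: AnatomyModel) -> list[Truss]:
    """One truss per ligament fascicle, embedded at its attachment points.

    Capsular fascicles stay on nearest-node snapping restricted to the
    articular blocks: their endpoints straddle the joint gap, which is
    split in the lattice, so a cell embedding could couple across the
    articulation.
    """
    trusses = []
    for lig in model.ligaments:
        card = MATERIALS[lig.group]
        area = card.cross_sectional_area / FASCICLES_PER_LEVEL[lig.group]
        label = f"ligament {lig.group}/{lig.level}/{lig.side}"
        if lig.group == "CL":
            n1, d1 = _nearest_node(mesh.nodes, lig.p_cranial)
            n2, d2 = _nearest_node(mesh.nodes, lig.p_caudal)
            worst = max(d1, d2)
            if worst > MAX_ATTACH_DISTANCE:
                raise ValueError(
                    f"{label}: attachment {worst:.1f} mm from the nearest "
                    f"node (> {MAX_ATTACH_DISTANCE} mm)")
            if n1 == n2:
                raise ValueError(f"{label} collapsed to a single node; "
                                 f"refine the mesh")
            trusses.append(Truss(n1, n2, card.young_modulus, area,
                                 lig.group, lig.level, lig.side, lig.index))
            continue
        n1, s1, w1 = _resolve_end(mesh, lig.p_cranial, label)
        n2, s2, w2 = _resolve_end(mesh, lig.p_caudal, label)
        trusses.append(Truss(
            n1, n2, card.young_modulus, area, lig.group, lig.level,
            lig.side, lig.index,
            p1=np.asarray(lig.p_cranial, float),
            p2=np.asarray(lig.p_caudal, float),
            support1=s1, w1=w1, support2=s2, w2=w2))
    return trusses


def annulus_fiber_trusses(mesh: LatticeMesh, model: AnatomyModel,
                          n_stations: int = 16) -> list[Truss]:
    """Criss-crossing fiber families on each annulus perimeter.

    Stations ring the annulus at the two endplate interfaces; family one
    connects station i (bottom) to station i+1 (top), family two the
    mirror, giving fibers inclined roughly +-30 degrees for the default
    disc proportions.
    """
    card = MATERIALS["annulus_fiber"]
    trusses = []
    for disc in ("L3L4", "L4L5"):
        region = model.regions[f"disc_{disc}_annulus"]
        outer = region.pos[0]
        poly = outer._cross_section
        z0, z1 = outer._z_range
        tf = outer._transform
        annulus_nodes = np.unique(
            mesh.tets[mesh.region_of_tet == f"disc_{disc}_annulus"])
        if len(annulus_nodes) == 0:
            continue
        theta = np.linspace(0, 2 * np.pi, n_stations, endpoint=False)
        # ring stations slightly inside the outer boundary
        ring = 0.96 * _polygon_points_at(poly, theta)
        bot = np.column_stack([ring, np.full(n_stations, z0)])
        top = np.column_stack([ring, np.full(n_stations, z1)])
        bot = bot @ tf[:3, :3].T + tf[:3, 3]
        top = top @ tf[:3, :3].T + tf[:3, 3]
        # nudge the ring stations just inside the core so the cell
        # embedding stays within the disc layers
        bot_in = bot + np.array([0.0, 0.0, 0.2])
        top_in = top - np.array([0.0, 0.0, 0.2])
        ends = [_resolve_end(mesh, q, f"fiber {disc}")
                for q in np.vstack([bot_in, top_in])]
        for i in range(n_stations):
            j = (i + 1) % n_stations
            pairs = (((i, bot_in[i]), (n_stations + j, top_in[j])),
                     ((j, bot_in[j]), (n_stations + i, top_in[i])))
            for k, ((ia, pa), (ib, pb)) in enumerate(pairs):
                (na, sa, wa), (nb, sb, wb) = ends[ia], ends[ib]
                if na == nb:
                    continue
                trusses.append(Truss(
                    na, nb, card.young_modulus,
                    card.cross_sectional_area, "annulus_fiber", disc,
                    "ring", 2 * i + k, p1=pa, p2=pb,
                    support1=sa, w1=wa, support2=sb, w2=wb,
                    tension_only=True))
    return trusses


def _polygon_points_at(poly: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Boundary points of a star-shaped polygon at given polar angles."""
    ang = np.arctan2(poly[:, 1], poly[:, 0])
    order = np.argsort(ang)
    ang_s = ang[order]
    pts = poly[order]
    out = []
    for t in np.arctan2(np.sin(theta), np.cos(theta)):
        i = np.searchsorted(ang_s, t) % len(ang_s)
        out.append(pts[i])
    return np.asarray(out)


#: fraction of the cartilage shear stiffness G*A/t carried tangentially
#: by an intact articulation.  A synovial joint slides far more freely
#: than a bonded cartilage layer would; the default is set so the intact
#: segment's rotations fall inside the published physiological corridor.
FACET_TANGENTIAL_FRACTION = 1.0


#: caudo-cranial obliquity of the effective articular contact normal, in
#: degrees.  The articular surfaces are curved, so their mean contact
#: normal is not horizontal: the upward component lets the joint carry
#: compression when the upper facet rides down in extension (facet
#: abutment) while separating freely in flexion.
FACET_NORMAL_TILT_DEG = 25.0


def facet_joint_springs(mesh: LatticeMesh, model: AnatomyModel,
                        n_tangent: int = 6, n_vertical: int = 6,
                        tangential_fraction: float | None = None,
                        normal_tilt_deg: float | None = None,
                        ) -> list[JointSpring]:
    """Compression-gated spring grid bridging each facet joint."""
    if tangential_fraction is None:
        tangential_fraction = FACET_TANGENTIAL_FRACTION
    if normal_tilt_deg is None:
        normal_tilt_deg = FACET_NORMAL_TILT_DEG
    card = MATERIALS["cartilage"]
    p = model.params
    springs = []
    for disc in ("L3L4", "L4L5"):
        cranial, caudal = disc[:2], disc[2:]
        sap_nodes = np.unique(
            mesh.tets[mesh.region_of_tet == f"{caudal}_posterior_elements"])
        iap_nodes = np.unique(
            mesh.tets[mesh.region_of_tet == f"{cranial}_posterior_elements"])
        for side in ("right", "left"):
            center = model.landmarks[f"facet_{disc}_{side}_center"]
            normal = model.landmarks[f"facet_{disc}_{side}_normal"]
            tangent = np.cross(np.array([0.0, 0.0, 1.0]), normal)
            tangent /= np.linalg.norm(tangent)
            a = np.linspace(-0.4, 0.4, n_tangent) * p.facet_width
            b = np.linspace(-0.4, 0.4, n_vertical) * p.facet_height
            area_trib = (p.facet_width * p.facet_height) \
                / (n_tangent * n_vertical)
            thickness = p.cartilage_thickness + p.facet_gap
            k = card.young_modulus * area_trib / thickness
            shear_modulus = card.young_modulus \
                / (2.0 * (1.0 + card.poisson_ratio))
            k_t = tangential_fraction * shear_modulus * area_trib \
                / thickness
            reach = p.facet_thickness / 2.0 + 1.0
            remap = (mesh.split_remaps or {}).get(cranial)
            for da in a:
                for db in b:
                    pt = center + da * tangent \
                        + db * np.array([0.0, 0.0, 1.0])
                    p_sap = pt - reach * normal
                    p_iap = pt + reach * normal
                    a_sap = mesh.anchor_at(p_sap)
                    a_iap = mesh.anchor_at(p_iap)
                    if a_sap is None or a_iap is None:
                        n_sap, d1 = _nearest_node(mesh.nodes, p_sap,
                                                  sap_nodes)
                        n_iap, d2 = _nearest_node(mesh.nodes, p_iap,
                                                  iap_nodes)
                        if n_sap == n_iap \
                                or max(d1, d2) > 4.0 * mesh.spacing:
                            continue
                        s1 = np.array([n_sap])
                        w1 = np.array([1.0])
                        s2 = np.array([n_iap])
                        w2 = np.array([1.0])
                    else:
                        s1, w1 = a_sap
                        s2, w2 = a_iap
                        # the cranial block's nodes were duplicated by the
                        # joint split; redirect the IAP-side supports
                        if remap is not None:
                            s2 = remap[s2]
                        n_sap = int(s1[np.argmax(w1)])
                        n_iap = int(s2[np.argmax(w2)])
                    tilt = np.radians(normal_tilt_deg)
                    d_eff = np.cos(tilt) * normal \
                        + np.sin(tilt) * np.array([0.0, 0.0, 1.0])
                    springs.append(JointSpring(
                        n_sap, n_iap, k, d_eff, pt.copy(),
                        joint=f"{disc}_{side}",
                        tangential_stiffness=k_t,
                        support1=s1, w1=w1, support2=s2, w2=w2))
    return springs


def build_fe_model(model: AnatomyModel, target_edge_mm: float = 3.0,
                   facet_tangential_fraction: float | None = None,
                   ) -> FEModel:
    """Intact (M1) finite-element model of the L3-L5 phantom."""
    mesh = tetrahedralize(model, target_edge_mm)
    trusses = attach_ligaments(mesh, model)
    trusses += annulus_fiber_trusses(mesh, model)
    springs = facet_joint_springs(
        mesh, model, tangential_fraction=facet_tangential_fraction)
    fem = FEModel(mesh=mesh, trusses=trusses, springs=springs,
                  fixed_nodes=mesh.node_sets["fixed"],
                  load_nodes=mesh.node_sets["load"])
    _prune_disconnected(fem)
    _drop_orphans(fem)
    fem.validate()
    return fem


def _drop_orphans(fem: FEModel) -> None:
    """Renumber nodes so only referenced ones remain."""
    referenced = np.unique(np.concatenate(
        [fem.mesh.tets.ravel()]
        + [np.array(t.all_nodes()) for t in fem.trusses]
        + [np.array(s.all_nodes()) for s in fem.springs]
        + [fem.fixed_nodes, fem.load_nodes]))
    remap = -np.ones(len(fem.mesh.nodes), dtype=np.int64)
    remap[referenced] = np.arange(len(referenced))
    fem.mesh.nodes = fem.mesh.nodes[referenced]
    fem.mesh.tets = remap[fem.mesh.tets]
    for t in fem.trusses:
        t.n1, t.n2 = int(remap[t.n1]), int(remap[t.n2])
        if t.embedded:
            t.support1 = remap[t.support1]
            t.support2 = remap[t.support2]
    for s in fem.springs:
        s.n1, s.n2 = int(remap[s.n1]), int(remap[s.n2])
        if s.embedded:
            s.support1 = remap[s.support1]
            s.support2 = remap[s.support2]
    fem.fixed_nodes = remap[fem.fixed_nodes]
    fem.load_nodes = remap[fem.load_nodes]
    for key, val in fem.mesh.node_sets.items():
        kept = remap[val]
        fem.mesh.node_sets[key] = kept[kept >= 0]


def apply_variant(fem: FEModel, model: AnatomyModel,
                  variant: SurgicalVariant) -> FEModel:
    """Derive a surgical model from the intact one.

    M1 is returned unchanged (same object); any other variant gets a deep
    element-level copy with bone tets, capsular fascicles, flavum trusses
    and facet springs removed according to the recipe.
    """
    variant.validate()
    if (variant.trephine is None
            and variant.capsular_fraction_removed == 0
            and variant.flavum_removed == "none"
            and variant.cartilage_removal == "none"):
        return fem
    frame = plan_frame(model)
    tools = plan_tools(frame, variant.trephine) if variant.trephine else []

    mesh = fem.mesh
    new_mesh = LatticeMesh(
        nodes=mesh.nodes.copy(), tets=mesh.tets.copy(),
        region_of_tet=mesh.region_of_tet.copy(),
        young=mesh.young.copy(), poisson=mesh.poisson.copy(),
        spacing=mesh.spacing,
        node_sets={k: v.copy() for k, v in mesh.node_sets.items()})
    report: dict = {"variant": variant.id}

    # --- element death inside the trephine barrel(s), bone regions only ---
    if tools:
        centroids = new_mesh.nodes[new_mesh.tets].mean(axis=1)
        in_tool = np.zeros(len(new_mesh.tets), dtype=bool)
        for tool in tools:
            in_tool |= tool.contains(centroids)
        resectable = np.array(
            [name.endswith(("cortical", "cancellous", "posterior_elements"))
             for name in new_mesh.region_of_tet])
        kill = in_tool & resectable
        report["tets_removed"] = int(kill.sum())
        report["removed_bone_volume_mm3"] = float(
            new_mesh.tet_volumes[kill].sum())
        keep = ~kill
        new_mesh.tets = new_mesh.tets[keep]
        new_mesh.region_of_tet = new_mesh.region_of_tet[keep]
        new_mesh.young = new_mesh.young[keep]
        new_mesh.poisson = new_mesh.poisson[keep]

    # --- ligament removal --------------------------------------------------
    trusses = [replace(t,
                       support1=None if t.support1 is None
                       else t.support1.copy(),
                       support2=None if t.support2 is None
                       else t.support2.copy())
               for t in fem.trusses]
    if variant.capsular_fraction_removed > 0:
        n_remove = round(4 * variant.capsular_fraction_removed)
        side = variant.trephine.side if variant.trephine else "right"
        cl = [t for t in trusses
              if t.group == "CL" and t.level == "L4L5" and t.side == side]
        axis_pt, axis_dir = trephine_axis(
            frame, variant.trephine.angle_deg, 1, side)
        def axis_distance(t: Truss) -> float:
            mid = 0.5 * (mesh.nodes[t.n1] + mesh.nodes[t.n2])
            rel = mid - axis_pt
            return float(np.linalg.norm(rel - (rel @ axis_dir) * axis_dir))
        cl.sort(key=axis_distance)
        doomed = {id(t) for t in cl[:n_remove]}
        trusses = [t for t in trusses if id(t) not in doomed]
        report["capsular_removed"] = n_remove
    if variant.flavum_removed == "right":
        before = len(trusses)
        trusses = [t for t in trusses
                   if not (t.group == "LF" and t.level == "L4L5"
                           and t.side == "right")]
        report["flavum_removed"] = before - len(trusses)

    # --- facet cartilage removal ------------------------------------------
    # removing cartilage strips the articulation of its shear grip (the
    # tangential spring term) but bone-on-bone contact persists wherever
    # the processes themselves survive, so the compression-gated normal
    # term is retained; springs whose bony attachment was resected are
    # dropped below with the detached-element filter
    springs = [replace(s, direction=s.direction.copy(),
                       sample_point=s.sample_point.copy(),
                       support1=None if s.support1 is None
                       else s.support1.copy(),
                       support2=None if s.support2 is None
                       else s.support2.copy())
               for s in fem.springs]
    side = variant.trephine.side if variant.trephine else "right"
    removed_springs = 0
    for s in springs:
        if s.joint != f"L4L5_{side}":
            continue
        stripped = variant.cartilage_removal == "extensive" or (
            tools and any(tool.contains(s.sample_point[None])[0]
                          for tool in tools))
        if stripped and s.tangential_stiffness > 0:
            s.tangential_stiffness = 0.0
            removed_springs += 1
    report["springs_removed"] = removed_springs
    n_joint_springs = sum(1 for s in fem.springs
                          if s.joint == f"L4L5_{side}")

    # trusses/springs only provide rank-one stiffness: an endpoint whose
    # solid elements were all resected would leave the system singular
    in_solid = np.zeros(len(new_mesh.nodes), dtype=bool)
    in_solid[new_mesh.tets] = True
    n_tr = len(trusses)
    trusses = [t for t in trusses
               if all(in_solid[n] for n in t.all_nodes())]
    n_sp = len(springs)
    springs = [s for s in springs
               if all(in_solid[n] for n in s.all_nodes())]
    report["detached_trusses"] = n_tr - len(trusses)
    report["detached_springs"] = n_sp - len(springs)
    # articulation area lost: exact tool-footprint area on the joint
    # mid-plane (whole articular surface for the extensive grade, which
    # destroys the articulation beyond the barrel footprint)
    if variant.cartilage_removal == "extensive":
        report["removed_cartilage_area_mm2"] = float(
            model.params.facet_width * model.params.facet_height)
    elif tools:
        report["removed_cartilage_area_mm2"] = \
            removed_cartilage_footprint_area(model, "L4L5", side, tools)
    else:
        report["removed_cartilage_area_mm2"] = 0.0

    out = FEModel(mesh=new_mesh, trusses=trusses, springs=springs,
                  fixed_nodes=new_mesh.node_sets["fixed"].copy(),
                  load_nodes=new_mesh.node_sets["load"].copy(),
                  variant_id=variant.id, removal_report=report)
    _prune_disconnected(out)
    _drop_orphans(out)
    out.validate()
    return out


def removed_cartilage_footprint_area(model: AnatomyModel, disc: str,
                                     side: str,
                                     tools: list[ConvexSolid]) -> float:
    """Exact tool-footprint area on a facet joint's mid-plane (mm^2).

    The joint plane is parametrised by its in-plane tangent and the
    vertical; each convex barrel restricted to that plane is a convex
    2-D region, clipped against the articular rectangle and united across
    attempts.
    """
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    p = model.params
    center = model.landmarks[f"facet_{disc}_{side}_center"]
    normal = model.landmarks[f"facet_{disc}_{side}_normal"]
    t1 = np.cross([0.0, 0.0, 1.0], normal)
    t1 /= np.linalg.norm(t1)
    t2 = np.array([0.0, 0.0, 1.0])
    w2, h2 = p.facet_width / 2.0, p.facet_height / 2.0
    rect = [(-w2, -h2), (w2, -h2), (w2, h2), (-w2, h2)]
    pieces = []
    for tool in tools:
        poly = [np.array(q, float) for q in rect]
        for a_row, b_val in zip(tool.A, tool.b):
            # half-space restricted to the plane: (a.t1) s + (a.t2) r
            #   <= b - a.center
            an = np.array([a_row @ t1, a_row @ t2])
            off = b_val - a_row @ center
            nrm = np.linalg.norm(an)
            if nrm < 1e-12:
                if off < 0:   # plane entirely outside this half-space
                    poly = []
                    break
                continue
            poly = _clip_poly2d(poly, an / nrm, off / nrm)
            if len(poly) < 3:
                break
        if len(poly) >= 3:
            pieces.append(Polygon(poly))
    if not pieces:
        return 0.0
    return float(unary_union(pieces).area)


def _clip_poly2d(pts, normal, offset):
    """Sutherland-Hodgman clip of a 2-D polygon by normal.x <= offset."""
    if not len(pts):
        return []
    d = [float(q @ normal - offset) for q in pts]
    out = []
    n = len(pts)
    for i in range(n):
        j = (i + 1) % n
        if d[i] <= 1e-12:
            out.append(pts[i])
        if (d[i] <= 1e-12) != (d[j] <= 1e-12):
            t = d[i] / (d[i] - d[j])
            out.append(pts[i] + t * (pts[j] - pts[i]))
    return out


def _prune_disconnected(fem: FEModel) -> None:
    """Remove floating or hinged fragments created by the resection.

    Connectivity is judged between solid elements sharing a triangular
    face: trusses and springs are rank-deficient and cannot stabilise a
    fragment, and tets touching only at a node or edge form zero-energy
    hinge mechanisms.  Fragments whose volume exceeds 1 % of the model are
    an error (the resection disconnected a vertebra); smaller slivers are
    dropped with a note in the removal report.
    """
    tets = fem.mesh.tets
    n_tet = len(tets)
    faces = np.sort(tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]],
                    axis=2).reshape(-1, 3)
    owner = np.repeat(np.arange(n_tet), 4)
    order = np.lexsort(faces.T)
    faces_s, owner_s = faces[order], owner[order]
    same = np.all(faces_s[1:] == faces_s[:-1], axis=1)
    pairs = np.column_stack([owner_s[:-1][same], owner_s[1:][same]])
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n_tet, n_tet))
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        # the grounded component is the one holding the fixed surface
        fixed_set = set(fem.fixed_nodes.tolist())
        grounded = next(comp[i] for i in range(n_tet)
                        if fixed_set.intersection(tets[i].tolist()))
        loose = comp != grounded
        loose_vol = float(fem.mesh.tet_volumes[loose].sum())
        total_vol = float(fem.mesh.tet_volumes.sum())
        if loose_vol > 0.01 * total_vol:
            raise ValueError(
                f"resection disconnected {loose_vol:.0f} mm^3 "
                f"({100 * loose_vol / total_vol:.1f} % of the model)")
        if loose.any():
            fem.removal_report["dropped_fragment_mm3"] = loose_vol
            keep = ~loose
            fem.mesh.tets = fem.mesh.tets[keep]
            fem.mesh.region_of_tet = fem.mesh.region_of_tet[keep]
            fem.mesh.young = fem.mesh.young[keep]
            fem.mesh.poisson = fem.mesh.poisson[keep]
    keep_nodes = np.zeros(len(fem.mesh.nodes), dtype=bool)
    keep_nodes[fem.mesh.tets] = True
    fem.trusses = [t for t in fem.trusses
                   if all(keep_nodes[n] for n in t.all_nodes())]
    fem.springs = [s for s in fem.springs
                   if all(keep_nodes[n] for n in s.all_nodes())]
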