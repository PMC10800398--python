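"""Parametric synthetic L3-L5 anatomy.

Generates a seeded three-level lumbar phantom (vertebral bodies with a
cortical shell, posterior elements, two discs with annulus/nucleus and
cartilage endplates, facet joints, and seven ligament groups) that stands in
for patient CT reconstructions.  The phantom honours the published geometric
specification of the segment it emulates:

* cortical shell thickness ~1 mm,
* disc complex cross-section ~95 % of the vertebral cross-section,
* nucleus cross-section 40 % of the disc, placed so the anterior/posterior
  annulus-edge-to-nucleus distance ratio is 1.62,
* facet cartilage thinner than 1 mm.

Frame convention: +x right, +y anterior, +z cranial, units mm, with the
center of the L4/5 disc near the origin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString, Polygon

from .convex import (
    ConvexSolid,
    RegionSolid,
    offset_polygon_inward,
    rectangle_polygon,
    superellipse_polygon,
)

VERTEBRAE = ("L3", "L4", "L5")
DISCS = ("L3L4", "L4L5")


@dataclass
class SubjectParams:
    """Geometric parameters of one synthetic subject (lengths in mm).

    The published source of this model states only the cross-sectional
    ratios, the cortical thickness and the cartilage thickness; absolute
    vertebral dimensions are design inputs taken from standard lumbar
    morphometry and are fully exposed here.
    """

    vertebral_body_width: float = 45.0
    vertebral_body_depth: float = 33.0
    vertebral_body_height: float = 27.0
    disc_height: float = 10.0
    endplate_thickness: float = 1.0
    lamina_thickness: float = 5.0
    lamina_height: float = 14.0
    lamina_halfwidth: float = 16.0
    lamina_lip_halfwidth: float = 10.0
    spinous_process_length: float = 25.0
    transverse_process_length: float = 14.0
    pedicle_width: float = 9.0
    pedicle_height: float = 11.0
    pedicle_length: float = 10.0
    pedicle_lateral_center: float = 14.0
    facet_gap: float = 0.4
    facet_angle: float = 20.0           # joint-plane rotation away from coronal, deg
    facet_width: float = 11.0
    facet_height: float = 14.0
    facet_thickness: float = 7.0
    facet_lateral_center: float = 12.0
    facet_posterior_offset: float = 13.0  # behind the disc posterior edge
    lordosis_angle_per_level: float = 0.0
    cortical_thickness: float = 1.0
    nucleus_area_fraction: float = 0.40
    disc_to_vertebra_area_fraction: float = 0.95
    ap_offset_ratio: float = 1.62
    cartilage_thickness: float = 0.8
    superellipse_exponent: float = 2.5
    section_vertices: int = 64
    rng_seed: int = 0

    _LENGTH_FIELDS = (
        "vertebral_body_width", "vertebral_body_depth",
        "vertebral_body_height", "disc_height", "endplate_thickness",
        "lamina_thickness", "lamina_height", "lamina_halfwidth",
        "lamina_lip_halfwidth", "spinous_process_length",
        "transverse_process_length", "pedicle_width", "pedicle_height",
        "pedicle_length", "pedicle_lateral_center", "facet_gap",
        "facet_width", "facet_height", "facet_thickness",
        "facet_lateral_center", "facet_posterior_offset",
        "cortical_thickness", "cartilage_thickness",
    )

    def validate(self) -> None:
        for name in self._LENGTH_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if not 0 < self.disc_to_vertebra_area_fraction <= 1:
            raise ValueError("disc_to_vertebra_area_fraction must be in (0, 1]")
        if self.cartilage_thickness >= 1.0:
            raise ValueError("cartilage_thickness must be < 1 mm")
        if self.ap_offset_ratio <= 0:
            raise ValueError("ap_offset_ratio must be positive")
        if self.disc_height <= 2 * self.endplate_thickness:
            raise ValueError("disc_height must exceed both endplates")
        if 2 * self.cortical_thickness >= min(self.vertebral_body_width,
                                              self.vertebral_body_depth,
                                              self.vertebral_body_height):
            raise ValueError("cortical_thickness collapses the cancellous core")


@dataclass
class CohortSpec:
    """Recipe for a jittered cohort of subjects (inter-patient variability)."""

    n_subjects: int = 25
    jitter: dict[str, float] = field(default_factory=lambda: dict(
        DEFAULT_JITTER_CV))
    master_seed: int = 0
    base_params: SubjectParams | None = None
    max_retries: int = 100

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for key, cv in self.jitter.items():
            if cv < 0:
                raise ValueError(f"jitter CV for {key} must be >= 0")
            if key not in {f.name for f in dataclasses.fields(SubjectParams)}:
                raise ValueError(f"unknown parameter {key!r} in jitter map")


#: Default per-parameter coefficients of variation for cohort sampling.
#: Applied to the skeletal dimensions only; the cross-sectional ratios are
#: modelling constants shared by all subjects.
DEFAULT_JITTER_CV = {
    "vertebral_body_width": 0.05,
    "vertebral_body_depth": 0.05,
    "vertebral_body_height": 0.05,
    "disc_height": 0.08,
    "lamina_thickness": 0.06,
    "lamina_height": 0.06,
    "spinous_process_length": 0.06,
    "pedicle_width": 0.05,
    "pedicle_height": 0.05,
    "facet_width": 0.06,
    "facet_height": 0.06,
    "facet_lateral_center": 0.04,
    "facet_posterior_offset": 0.05,
    "facet_angle": 0.06,
}


@dataclass
class LigamentAttachment:
    """One ligament fascicle: a named attachment-point pair."""

    group: str       # ALL, PLL, LF, ISL, SSL, ITL, CL
    level: str       # L3L4 or L4L5
    side: str        # left / right / midline
    index: int
    p_cranial: np.ndarray
    p_caudal: np.ndarray


@dataclass
class AnatomyModel:
    """One synthetic subject: exact regional solids plus derived meshes."""

    params: SubjectParams
    regions: dict[str, RegionSolid]
    landmarks: dict[str, np.ndarray]
    ligaments: list[LigamentAttachment]
    disc_frames: dict[str, dict[str, np.ndarray]]
    _mesh_cache: dict[str, trimesh.Trimesh] = field(default_factory=dict)

    def region_mesh(self, name: str) -> trimesh.Trimesh:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}")
        if name not in self._mesh_cache:
            self._mesh_cache[name] = self.regions[name].to_mesh()
        return self._mesh_cache[name]

    @property
    def meshes(self) -> dict[str, trimesh.Trimesh]:
        return {name: self.region_mesh(name) for name in self.regions}

    def bone_region_names(self) -> list[str]:
        return [n for n in self.regions
                if n.endswith(("cortical", "cancellous", "posterior_elements"))]

    def cartilage_region_names(self) -> list[str]:
        return [n for n in self.regions if n.startswith("facet_cartilage")]


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _level_transform(angle_deg: float, pivot: np.ndarray) -> np.ndarray:
    """Rigid rotation about +x through a pivot (lordotic tilt of one level)."""
    t = np.eye(4)
    a = np.radians(angle_deg)
    R = np.array([[1, 0, 0],
                  [0, np.cos(a), -np.sin(a)],
                  [0, np.sin(a), np.cos(a)]])
    t[:3, :3] = R
    t[:3, 3] = pivot - R @ pivot
    return t


def generate_phantom(params: SubjectParams) -> AnatomyModel:
    """Build the L3-L5 phantom for one subject.

    Deterministic: the output is a pure function of ``params`` (the seed is
    carried for provenance and cohort bookkeeping).  Raises ``ValueError``
    naming the offending region for degenerate parameter combinations.
    """
    params.validate()
    p = params

    a_v = p.vertebral_body_width / 2.0
    b_v = p.vertebral_body_depth / 2.0
    h_v = p.vertebral_body_height
    n_pts = p.section_vertices
    exp = p.superellipse_exponent

    body_poly = superellipse_polygon(a_v, b_v, exp, n_pts)
    disc_scale = np.sqrt(p.disc_to_vertebra_area_fraction)
    disc_poly = body_poly * disc_scale
    nucleus_scale = np.sqrt(p.nucleus_area_fraction)
    b_d = b_v * disc_scale
    # place the nucleus so that (anterior edge -> centroid)/(centroid ->
    # posterior edge) equals the requested anterior/posterior ratio
    r = p.ap_offset_ratio
    y_n = b_d * (1.0 - r) / (1.0 + r)
    nucleus_poly = disc_poly * nucleus_scale + np.array([0.0, y_n])
    b_nuc = b_d * nucleus_scale
    if y_n - b_nuc <= -b_d or y_n + b_nuc >= b_d:
        raise ValueError("nucleus: requested fractions push the nucleus "
                         "outside the annulus boundary")
    try:
        inner_poly = offset_polygon_inward(body_poly, p.cortical_thickness)
    except ValueError as exc:
        raise ValueError(f"cortical: {exc}") from exc

    # vertical stack (before lordotic tilt): L4/5 disc centered at z = 0
    d = p.disc_height
    z_l5 = (-d / 2.0 - h_v, -d / 2.0)
    z_l4 = (d / 2.0, d / 2.0 + h_v)
    z_l3 = (d / 2.0 + h_v + d, d / 2.0 + 2.0 * h_v + d)
    body_z = {"L5": z_l5, "L4": z_l4, "L3": z_l3}
    disc_z = {"L4L5": (-d / 2.0, d / 2.0),
              "L3L4": (d / 2.0 + h_v, d / 2.0 + h_v + d)}

    # cumulative lordotic tilt: each disc tilts everything cranial to it
    transforms = {"L5": np.eye(4), "L4": np.eye(4), "L3": np.eye(4)}
    disc_tf = {"L4L5": np.eye(4), "L3L4": np.eye(4)}
    if p.lordosis_angle_per_level != 0.0:
        pivot_45 = np.array([0.0, 0.0, 0.0])
        t45 = _level_transform(p.lordosis_angle_per_level, pivot_45)
        pivot_34 = np.array([0.0, 0.0, np.mean(disc_z["L3L4"])])
        t34 = _level_transform(p.lordosis_angle_per_level, pivot_34)
        transforms["L4"] = t45
        disc_tf["L3L4"] = t45
        transforms["L3"] = t45 @ t34
        # the half-tilt of each disc wedge is absorbed rigidly; the discs
        # themselves stay prisms tilted with their caudal vertebra's frame
        disc_tf["L4L5"] = _level_transform(p.lordosis_angle_per_level / 2.0,
                                           pivot_45)
        disc_tf["L3L4"] = t45 @ _level_transform(
            p.lordosis_angle_per_level / 2.0, pivot_34)

    regions: dict[str, RegionSolid] = {}
    landmarks: dict[str, np.ndarray] = {}
    ligaments: list[LigamentAttachment] = []
    disc_frames: dict[str, dict[str, np.ndarray]] = {}

    def tf_point(tf: np.ndarray, point) -> np.ndarray:
        point = np.asarray(point, float)
        return tf[:3, :3] @ point + tf[:3, 3]

    # ---- vertebral bodies ------------------------------------------------
    for name in VERTEBRAE:
        z0, z1 = body_z[name]
        tf = transforms[name]
        outer = ConvexSolid.from_extrusion(body_poly, z0, z1, tf,
                                           name=f"{name}_body_outer")
        inner = ConvexSolid.from_extrusion(
            inner_poly, z0 + p.cortical_thickness, z1 - p.cortical_thickness,
            tf, name=f"{name}_body_inner")
        regions[f"{name}_cortical"] = RegionSolid(
            f"{name}_cortical", pos=[outer], neg=[inner])
        regions[f"{name}_cancellous"] = RegionSolid(
            f"{name}_cancellous", pos=[inner])
        regions[f"{name}_posterior_elements"] = _posterior_elements(
            p, name, z0, z1, tf, b_v)

    # ---- discs and endplates --------------------------------------------
    for disc in DISCS:
        z0, z1 = disc_z[disc]
        tf = disc_tf[disc]
        te = p.endplate_thickness
        core = ConvexSolid.from_extrusion(disc_poly, z0 + te, z1 - te, tf,
                                          name=f"disc_{disc}_outer")
        nucleus = ConvexSolid.from_extrusion(nucleus_poly, z0 + te, z1 - te,
                                             tf, name=f"disc_{disc}_nucleus")
        regions[f"disc_{disc}_annulus"] = RegionSolid(
            f"disc_{disc}_annulus", pos=[core], neg=[nucleus])
        regions[f"disc_{disc}_nucleus"] = RegionSolid(
            f"disc_{disc}_nucleus", pos=[nucleus])

        cranial, caudal = disc[:2], disc[2:]
        ep_lo = ConvexSolid.from_extrusion(disc_poly, z0, z0 + te, tf,
                                           name=f"endplate_{caudal}_superior")
        ep_hi = ConvexSolid.from_extrusion(disc_poly, z1 - te, z1, tf,
                                           name=f"endplate_{cranial}_inferior")
        regions[f"endplate_{caudal}_superior"] = RegionSolid(
            f"endplate_{caudal}_superior", pos=[ep_lo])
        regions[f"endplate_{cranial}_inferior"] = RegionSolid(
            f"endplate_{cranial}_inferior", pos=[ep_hi])

        landmarks[f"endplate_{caudal}_superior_posterior_midpoint"] = \
            tf_point(tf, [0.0, -b_d, z0])
        landmarks[f"endplate_{cranial}_inferior_posterior_midpoint"] = \
            tf_point(tf, [0.0, -b_d, z1])
        normal = tf[:3, :3] @ np.array([0.0, 0.0, 1.0])
        center = tf_point(tf, [0.0, 0.0, (z0 + z1) / 2.0])
        disc_frames[disc] = {"center": center, "normal": normal,
                             "mid_z": np.array([(z0 + z1) / 2.0]),
                             "transform": tf}

    # ---- facet joints and their cartilage --------------------------------
    for disc in DISCS:
        z_joint = float(np.mean(disc_z[disc]))
        tf = disc_tf[disc]
        cranial, caudal = disc[:2], disc[2:]
        for side, sx in (("right", 1.0), ("left", -1.0)):
            cart_parts, sap, iap, lm = _facet_complex(
                p, sx, z_joint, b_d, name=f"{disc}_{side}")
            cart_parts = [c.transformed(tf) for c in cart_parts]
            sap, iap = sap.transformed(tf), iap.transformed(tf)
            regions[f"facet_cartilage_{disc}_{side}"] = RegionSolid(
                f"facet_cartilage_{disc}_{side}", pos=cart_parts)
            regions[f"{caudal}_posterior_elements"].pos.append(sap)
            regions[f"{cranial}_posterior_elements"].pos.append(iap)
            landmarks[f"facet_{disc}_{side}_center"] = tf_point(
                tf, lm["center"])
            landmarks[f"facet_{disc}_{side}_normal"] = \
                tf[:3, :3] @ lm["normal"]
            # capsular ligaments: four fascicles ringing the joint
            for k, (dt, dz) in enumerate([(-0.35, -0.32), (0.35, -0.32),
                                          (0.35, 0.32), (-0.35, 0.32)]):
                off = (dt * p.facet_width * lm["tangent"]
                       + dz * p.facet_height * np.array([0.0, 0.0, 1.0]))
                reach = p.facet_gap / 2.0 + p.cartilage_thickness / 2.0 + 1.0
                p_iap = lm["center"] + reach * lm["normal"] + off
                p_sap = lm["center"] - reach * lm["normal"] + off
                ligaments.append(LigamentAttachment(
                    "CL", disc, side, k,
                    tf_point(tf, p_iap), tf_point(tf, p_sap)))

    # articular processes overlap the lamina lip / pedicle where the bone is
    # anatomically continuous (the pars region) -- and a vertebra's lamina
    # margin can reach the neighbouring vertebra's process; trim all other
    # parts against every articular process so the parts tile space without
    # double-counted volume and the joints stay open
    all_processes = [part
                     for name in VERTEBRAE
                     for part in regions[f"{name}_posterior_elements"].pos
                     if part.name.endswith(("_sap", "_iap"))]
    for name in VERTEBRAE:
        _disjointify_parts(regions[f"{name}_posterior_elements"],
                           all_processes)

    # ---- midline / paired ligaments per disc level ------------------------
    # attachment points sit on the bony structures of the two vertebrae
    for disc in DISCS:
        cranial, caudal = disc[:2], disc[2:]
        z0c, z1c = body_z[cranial]   # cranial vertebra body extent
        z0d, z1d = body_z[caudal]    # caudal vertebra body extent
        zc_cran = (z0c + z1c) / 2.0
        zc_caud = (z0d + z1d) / 2.0
        y_post_body = -b_v
        y_lam = -(b_v + p.pedicle_length + p.lamina_thickness / 2.0)
        y_spin_base = -(b_v + p.pedicle_length + p.lamina_thickness)
        y_spin_tip = y_spin_base - p.spinous_process_length
        x_tp = p.pedicle_lateral_center + p.pedicle_width / 2.0 \
            + p.transverse_process_length
        x_lf = p.lamina_lip_halfwidth * 0.8
        lam_top = lambda zc: zc - 2.0 + p.lamina_height / 2.0
        lip_bot_cran = z0c - 3.0
        pairs = {
            # anterior/posterior longitudinal: on the body walls, 2 mm past
            # the disc on each side
            "ALL": [("midline", [0.0, b_v - 1.0, z0c + 2.0],
                     [0.0, b_v - 1.0, z1d - 2.0])],
            "PLL": [("midline", [0.0, y_post_body + 1.0, z0c + 2.0],
                     [0.0, y_post_body + 1.0, z1d - 2.0])],
            # ligamentum flavum: cranial lamina lip margin to caudal lamina
            # superior margin, one fascicle per side
            "LF": [(side, [sx * x_lf, y_lam, lip_bot_cran + 0.5],
                    [sx * x_lf, y_lam, lam_top(zc_caud) - 0.5])
                   for side, sx in (("left", -1.0), ("right", 1.0))],
            # interspinous: adjacent spinous process margins
            "ISL": [("midline",
                     [0.0, (y_spin_base + y_spin_tip) / 2.0, zc_cran - 8.0],
                     [0.0, (y_spin_base + y_spin_tip) / 2.0,
                      zc_caud + 2.0])],
            # supraspinous: spinous process tips
            "SSL": [("midline", [0.0, y_spin_tip + 1.0, zc_cran - 3.0],
                     [0.0, y_spin_tip + 1.0, zc_caud - 3.0])],
            # intertransverse: transverse process tips
            "ITL": [(side, [sx * (x_tp - 1.0), -b_v - 2.0, zc_cran + 4.0],
                     [sx * (x_tp - 1.0), -b_v - 2.0, zc_caud + 4.0])
                    for side, sx in (("left", -1.0), ("right", 1.0))],
        }
        for group, entries in pairs.items():
            for k, (side, top, bot) in enumerate(entries):
                top = tf_point(transforms[cranial], np.asarray(top, float))
                bot = tf_point(transforms[caudal], np.asarray(bot, float))
                ligaments.append(LigamentAttachment(group, disc, side, k,
                                                    top, bot))
                landmarks[f"lig_{group}_{disc}_{side}_{k}_cranial"] = top
                landmarks[f"lig_{group}_{disc}_{side}_{k}_caudal"] = bot

    model = AnatomyModel(params=p, regions=regions, landmarks=landmarks,
                         ligaments=ligaments, disc_frames=disc_frames)
    _check_model(model)
    return model


def _posterior_elements(p: SubjectParams, name: str, z0: float, z1: float,
                        tf: np.ndarray, b_v: float) -> RegionSolid:
    """Pedicles, lamina (with caudal lip), spinous and transverse processes.

    Articular processes are appended separately per facet joint.  Parts abut
    on shared planes so the union is connected but not overlapping.
    """
    zc = (z0 + z1) / 2.0
    parts: list[ConvexSolid] = []
    embed = 2.0  # pedicle root reaches into the (curved) body wall
    y_ped0 = -(b_v + p.pedicle_length)
    y_ped1 = -b_v + embed
    for sx in (-1.0, 1.0):
        ped = rectangle_polygon(p.pedicle_width, p.pedicle_height,
                                (sx * p.pedicle_lateral_center, zc + 4.0))
        parts.append(_extrude_along_y(ped, y_ped0, y_ped1,
                                      name=f"{name}_pedicle"))
        tp = rectangle_polygon(6.0, 7.0, (-b_v - 2.0, zc + 4.0))
        x0 = sx * (p.pedicle_lateral_center + p.pedicle_width / 2.0)
        x1 = x0 + sx * p.transverse_process_length
        parts.append(_extrude_along_x(tp, min(x0, x1), max(x0, x1),
                                      name=f"{name}_transverse"))
    y_lam1 = y_ped0
    y_lam0 = y_lam1 - p.lamina_thickness
    lam = rectangle_polygon(2 * p.lamina_halfwidth, p.lamina_height,
                            (0.0, zc - 2.0))
    parts.append(_extrude_along_y(lam, y_lam0, y_lam1,
                                  name=f"{name}_lamina"))
    # caudal lamina lip: the inferior lamina margin overhangs the interspace
    lip_top = zc - 2.0 - p.lamina_height / 2.0
    lip_bot = z0 - 3.0
    if lip_bot < lip_top:
        lip = rectangle_polygon(2 * p.lamina_lip_halfwidth,
                                lip_top - lip_bot,
                                (0.0, (lip_top + lip_bot) / 2.0))
        parts.append(_extrude_along_y(lip, y_lam0, y_lam1,
                                      name=f"{name}_lamina_lip"))
    spin = rectangle_polygon(5.0, 12.0, (0.0, zc - 3.0))
    parts.append(_extrude_along_y(spin, y_lam0 - p.spinous_process_length,
                                  y_lam0, name=f"{name}_spinous"))
    return RegionSolid(f"{name}_posterior_elements",
                       pos=[part.transformed(tf) for part in parts])


def _extrude_along_y(poly_xz: np.ndarray, y0: float, y1: float,
                     name: str = "") -> ConvexSolid:
    """Extrude a polygon given in the world (x, z) plane along world +y."""
    # rotation (det +1): local (x, y, z) -> world (x, z, -y)
    t = np.eye(4)
    t[:3, :3] = np.array([[1.0, 0.0, 0.0],
                          [0.0, 0.0, 1.0],
                          [0.0, -1.0, 0.0]])
    poly_xz = np.asarray(poly_xz, float)
    # world (x, z) footprint -> local (x, -z); the sign flip mirrors the
    # polygon, so reverse the loop to keep it CCW in the local plane
    poly = np.column_stack([poly_xz[:, 0], -poly_xz[:, 1]])[::-1]
    return ConvexSolid.from_extrusion(poly, y0, y1, t, name=name)


def _extrude_along_x(poly_yz: np.ndarray, x0: float, x1: float,
                     name: str = "") -> ConvexSolid:
    """Extrude a polygon given in the world (y, z) plane along world +x."""
    # rotation (det +1): local x -> world y, local y -> world z,
    # local z -> world x
    t = np.eye(4)
    t[:3, :3] = np.array([[0.0, 0.0, 1.0],
                          [1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0]])
    return ConvexSolid.from_extrusion(np.asarray(poly_yz, float),
                                      x0, x1, t, name=name)


def _facet_complex(p: SubjectParams, sx: float, z_joint: float, b_d: float,
                   name: str):
    """One facet joint: cartilage pair, SAP (caudal) and IAP (cranial) bone.

    The joint plane contains the joint center; its normal ``u`` points from
    the superior-articular-process side (anterolateral) toward the
    inferior-articular-process side (posteromedial), mirrored for the left.
    """
    phi = np.radians(p.facet_angle)
    u = np.array([-sx * np.sin(phi), -np.cos(phi), 0.0])
    tangent = np.array([sx * np.cos(phi), -np.sin(phi), 0.0])
    center = np.array([sx * p.facet_lateral_center,
                       -b_d - p.facet_posterior_offset, z_joint])

    def slab(s0: float, s1: float, w: float, h: float, dz: float,
             label: str) -> ConvexSolid:
        # extrusion frame: local x = tangent, local y = world z, local z = u
        t = np.eye(4)
        t[:3, 0] = tangent
        t[:3, 1] = np.array([0.0, 0.0, 1.0])
        t[:3, 2] = u
        if np.linalg.det(t[:3, :3]) < 0:
            # mirror-symmetric rectangle: flipping local x keeps the shape
            # and restores a proper rotation
            t[:3, 0] = -t[:3, 0]
        poly = rectangle_polygon(w, h, (0.0, dz))
        t[:3, 3] = center
        return ConvexSolid.from_extrusion(poly, s0, s1, t,
                                          name=f"{name}_{label}")

    g2 = p.facet_gap / 2.0
    tc2 = p.cartilage_thickness / 2.0
    cart_sap = slab(-g2 - tc2, -g2, p.facet_width, p.facet_height, 0.0,
                    "cartilage_sap")
    cart_iap = slab(g2, g2 + tc2, p.facet_width, p.facet_height, 0.0,
                    "cartilage_iap")
    # bone blocks extend vertically past the joint to fuse with pedicle/lamina
    sap = slab(-g2 - tc2 - p.facet_thickness, -g2 - tc2,
               p.facet_width, p.facet_height + 10.0, -5.0, "sap")
    iap = slab(g2 + tc2, g2 + tc2 + p.facet_thickness,
               p.facet_width, p.facet_height + 10.0, 5.0, "iap")
    lm = {"center": center, "normal": u, "tangent": tangent}
    return [cart_sap, cart_iap], sap, iap, lm


def _disjointify_parts(region: RegionSolid,
                       processes: list[ConvexSolid]) -> None:
    """Trim a region's non-process parts against all articular processes.

    Processes keep their full shape (they are the resection-relevant
    geometry); other parts are cut back by exact convex difference wherever
    they overlap one, leaving the parts pairwise disjoint.
    """
    own = [q for q in region.pos if q.name.endswith(("_sap", "_iap"))]
    rest = [q for q in region.pos if q not in own]
    kept = list(own)
    for part in rest:
        pieces = [part]
        for keeper in processes:
            nxt: list[ConvexSolid] = []
            for piece in pieces:
                if piece.intersect(keeper).volume > 1e-9:
                    nxt.extend(piece.difference_pieces(keeper))
                else:
                    nxt.append(piece)
            pieces = nxt
        kept.extend(pieces)
    region.pos = kept


def _check_model(model: AnatomyModel) -> None:
    """Reject degenerate geometry, naming the offending region."""
    for name, region in model.regions.items():
        for part in region.pos + region.neg:
            if part.is_empty:
                raise ValueError(f"region {name}: empty solid {part.name!r}")
        if region.volume <= 0:
            raise ValueError(f"region {name}: non-positive volume")


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal basis (u, v) with v = projection of world +y."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    y = np.array([0.0, 1.0, 0.0])
    v = y - (y @ normal) * normal
    if np.linalg.norm(v) < 1e-8:
        v = np.array([1.0, 0.0, 0.0])
    v /= np.linalg.norm(v)
    u = np.cross(v, normal)
    return u, v


def _section_loops(mesh: trimesh.Trimesh, origin: np.ndarray,
                   normal: np.ndarray, region_name: str) -> list[Polygon]:
    """Closed cross-section loops of a mesh, as 2-D rings in plane coords.

    Plane coordinates: first axis = in-plane lateral direction, second axis
    = in-plane projection of world +y (anterior), so the mid-sagittal
    measurements read directly off the second coordinate.
    """
    section = mesh.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        raise ValueError(f"section plane misses region {region_name!r}")
    u, v = _plane_basis(normal)
    origin = np.asarray(origin, float)
    loops = []
    for pts in section.discrete:
        pts = np.asarray(pts, float)
        if len(pts) < 3:
            continue
        rel = pts - origin
        ring = np.column_stack([rel @ u, rel @ v])
        poly = Polygon(ring)
        if poly.area > 1e-9:
            loops.append(poly if poly.is_valid else poly.buffer(0))
    if not loops:
        raise ValueError(f"section of {region_name!r} produced no polygon")
    return loops


def _even_odd_area(loops: list[Polygon]) -> float:
    """Area of a region given its boundary rings (even-odd nesting)."""
    total = 0.0
    for i, poly in enumerate(loops):
        depth = sum(1 for j, other in enumerate(loops)
                    if j != i and other.contains(poly.representative_point())
                    and other.area > poly.area)
        total += poly.area if depth % 2 == 0 else -poly.area
    return total


def measure_area_fractions(model: AnatomyModel,
                           disc: str = "L4L5") -> dict[str, float]:
    """Measure the published cross-sectional ratios on the meshed phantom.

    All quantities are evaluated on the disc's mid-height section plane:

    * ``nucleus_over_disc`` -- nucleus area / (annulus + nucleus) area,
    * ``disc_over_vertebra`` -- disc complex area / caudal vertebral body
      cross-section at its superior surface,
    * ``ap_offset_ratio`` -- anterior-annulus-edge-to-nucleus-centroid over
      posterior-edge-to-centroid distance along the mid-sagittal line.
    """
    frame = model.disc_frames[disc]
    origin, normal = frame["center"], frame["normal"]

    nuc_loops = _section_loops(model.region_mesh(f"disc_{disc}_nucleus"),
                               origin, normal, f"disc_{disc}_nucleus")
    ann_loops = _section_loops(model.region_mesh(f"disc_{disc}_annulus"),
                               origin, normal, f"disc_{disc}_annulus")
    nucleus_area = _even_odd_area(nuc_loops)
    annulus_area = _even_odd_area(ann_loops)
    disc_area = annulus_area + nucleus_area

    caudal = disc[2:]
    body_mesh = model.region_mesh(f"{caudal}_cortical")
    # vertebral cross-section just below the caudal body's superior surface
    body_origin = origin - normal * (model.params.disc_height / 2.0 + 1.0)
    body_loops = _section_loops(body_mesh, body_origin, normal,
                                f"{caudal}_cortical")
    # cortical section is an annular ring: vertebral area = outer envelope
    body_area = max(poly.area for poly in body_loops)

    # mid-sagittal anterior/posterior annulus edges, in section-plane coords
    # (second plane coordinate is the anterior direction)
    exterior = max(ann_loops, key=lambda q: q.area)
    nuc_outer = max(nuc_loops, key=lambda q: q.area)
    cx, cy = nuc_outer.centroid.x, nuc_outer.centroid.y
    span = 10.0 * max(exterior.bounds[2] - exterior.bounds[0],
                      exterior.bounds[3] - exterior.bounds[1])
    line = LineString([(cx, cy - span), (cx, cy + span)])
    cut = exterior.intersection(line)
    if cut.is_empty:
        raise ValueError("mid-sagittal line misses the annulus section")
    coords = np.asarray(shapely.get_coordinates(cut))
    proj = coords[:, 1] - cy
    dist_anterior = float(proj.max())
    dist_posterior = float(-proj.min())
    return {
        "nucleus_over_disc": nucleus_area / disc_area,
        "disc_over_vertebra": disc_area / body_area,
        "ap_offset_ratio": dist_anterior / dist_posterior,
    }


def measure_cortical_thickness(model: AnatomyModel, vertebra: str = "L4",
                               n_rays: int = 180) -> float:
    """Median radial shell thickness of a vertebral body by ray casting."""
    region = model.regions[f"{vertebra}_cortical"]
    outer, inner = region.pos[0], region.neg[0]
    tf = outer._transform
    z_mid = np.mean(outer._z_range)
    center = tf[:3, :3] @ np.array([0.0, 0.0, z_mid]) + tf[:3, 3]
    theta = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta),
                            np.zeros(n_rays)]) @ tf[:3, :3].T
    thickness = []
    for direction in dirs:
        t_out = _ray_exit(outer, center, direction)
        t_in = _ray_exit(inner, center, direction)
        if t_out is not None and t_in is not None:
            thickness.append(t_out - t_in)
    if not thickness:
        raise ValueError("no rays crossed the cortical shell")
    return float(np.median(thickness))


def _ray_exit(solid: ConvexSolid, origin: np.ndarray,
              direction: np.ndarray) -> float | None:
    """Distance to where a ray from an interior point exits a convex solid."""
    denom = solid.A @ direction
    numer = solid.b - solid.A @ origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numer / denom
    t = t[denom > 1e-12]
    if len(t) == 0:
        return None
    t_exit = float(t.min())
    return t_exit if t_exit > 0 else None


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_cohort(spec: CohortSpec) -> list[SubjectParams]:
    """Draw jittered subject parameter sets (truncated-normal, per-parameter).

    Deterministic under ``master_seed``; invalid draws are resampled with a
    bounded retry budget.
    """
    spec.validate()
    base = spec.base_params or SubjectParams()
    rng = np.random.default_rng(spec.master_seed)
    subjects = []
    for i in range(spec.n_subjects):
        for attempt in range(spec.max_retries):
            draw = dataclasses.replace(base)
            for key, cv in spec.jitter.items():
                mean = getattr(base, key)
                value = rng.normal(mean, abs(mean) * cv)
                value = float(np.clip(value, mean * (1 - 2.5 * cv),
                                      mean * (1 + 2.5 * cv)))
                setattr(draw, key, value)
            draw.rng_seed = int(rng.integers(0, 2**31 - 1))
            try:
                draw.validate()
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"subject {i}: retry budget exhausted sampling valid "
                f"parameters")
        subjects.append(draw)
    return subjects
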