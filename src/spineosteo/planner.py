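"""Targeted-puncture geometry for trephine osteotomy at the L4/5 interspace.

Reconstructs the planning construction used clinically: least-squares
endplate planes, the interspace center point (midpoint of the posterior-edge
midpoints of the adjacent endplates), a reference plane through that center
parallel to the L5 superior endplate, and trephine axes drawn on that plane
at 20-70 degrees from the mid-sagittal (posterior-to-anterior) axis, opening
toward the approach side.  A second osteotomy attempt is the trajectory
rotated a further 5 degrees outward about the shared entry point, sweeping
the barrel across residual articular bone at the target depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyModel
from .convex import ConvexSolid

PEID_ANGLES = (20, 30, 40)
PTED_ANGLES = (50, 60, 70)
ALLOWED_ANGLES = PEID_ANGLES + PTED_ANGLES
ALLOWED_DIAMETERS = (7, 8, 9)
SECOND_ATTEMPT_OFFSET_DEG = 5.0


@dataclass
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        normal = np.asarray(self.normal, float)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        self.normal = normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class InterspaceFrame:
    """Planning frame at the L4/5 (or L3/4) interspace.

    ``central_axis`` points posterior within the reference plane (the
    direction from the interspace center toward the spinous process);
    ``lateral_axis`` points to the subject's right.
    """

    center: np.ndarray
    reference_plane: Plane
    central_axis: np.ndarray
    lateral_axis: np.ndarray

    def __post_init__(self):
        n = self.reference_plane.normal
        if abs(self.central_axis @ n) > 1e-9:
            raise ValueError("central_axis must lie in the reference plane")
        if abs(self.lateral_axis @ n) > 1e-9:
            raise ValueError("lateral_axis must lie in the reference plane")
        if abs(self.central_axis @ self.lateral_axis) > 1e-9:
            raise ValueError("frame axes must be orthogonal")


@dataclass
class TrephinePlan:
    """One planned osteotomy: approach side, entry angle, tool, attempts."""

    angle_deg: float
    diameter_mm: float
    attempts: int = 1
    side: str = "right"
    second_attempt_offset_deg: float = SECOND_ATTEMPT_OFFSET_DEG
    cylinder_length: float = 120.0
    offset_pivot: str = "entry"
    allow_nonstandard: bool = False

    def validate(self) -> None:
        if not self.allow_nonstandard:
            if self.angle_deg not in ALLOWED_ANGLES:
                raise ValueError(
                    f"angle {self.angle_deg} not in {ALLOWED_ANGLES}")
            if self.diameter_mm not in ALLOWED_DIAMETERS:
                raise ValueError(
                    f"diameter {self.diameter_mm} not in {ALLOWED_DIAMETERS}")
        if self.attempts not in (1, 2):
            raise ValueError("attempts must be 1 or 2")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.cylinder_length <= 0 or self.diameter_mm <= 0:
            raise ValueError("tool dimensions must be positive")
        if self.offset_pivot not in ("entry", "target"):
            raise ValueError("offset_pivot must be 'entry' or 'target'")

    @property
    def group(self) -> str:
        """Approach family implied by the entry angle."""
        return "PEID" if self.angle_deg <= 45 else "PTED"


def fit_endplate_plane(model: AnatomyModel, endplate_name: str) -> Plane:
    """Least-squares plane through an endplate's surface vertices.

    The normal is the smallest-singular-vector of the centered vertex cloud,
    oriented cranially (+z hemisphere).  Raises if the vertices are too few
    or collinear.
    """
    if endplate_name not in model.regions:
        raise KeyError(f"no endplate region {endplate_name!r}")
    verts = np.asarray(model.region_mesh(endplate_name).vertices, float)
    return fit_plane_to_points(verts)


def fit_plane_to_points(points: np.ndarray) -> Plane:
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9:
        raise ValueError("points are collinear; plane fit is degenerate")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    return Plane(point=centroid, normal=normal)


def build_interspace_frame(model: AnatomyModel,
                           cranial_inferior_plane: Plane,
                           caudal_superior_plane: Plane,
                           disc: str = "L4L5") -> InterspaceFrame:
    """Interspace center point and reference plane.

    Center = midpoint of the posterior-edge midpoints of the two adjacent
    endplates; the reference plane passes through the center parallel to the
    caudal vertebra's superior endplate.
    """
    cranial, caudal = disc[:2], disc[2:]
    key_hi = f"endplate_{cranial}_inferior_posterior_midpoint"
    key_lo = f"endplate_{caudal}_superior_posterior_midpoint"
    for key in (key_hi, key_lo):
        if key not in model.landmarks:
            raise KeyError(f"missing landmark {key!r}")
    center = 0.5 * (model.landmarks[key_hi] + model.landmarks[key_lo])
    normal = caudal_superior_plane.normal
    reference = Plane(point=center, normal=normal)
    # in-plane posterior axis: project -y onto the plane
    posterior = np.array([0.0, -1.0, 0.0])
    central = posterior - (posterior @ normal) * normal
    central /= np.linalg.norm(central)
    lateral = np.cross(central, normal)
    if lateral[0] < 0:
        lateral = -lateral
    return InterspaceFrame(center=center, reference_plane=reference,
                           central_axis=central, lateral_axis=lateral)


#: distance from the target point back to the shared skin-side entry
#: point, mm; also the default barrel overhang behind the target
ENTRY_DISTANCE = 60.0


def trephine_axis(frame: InterspaceFrame, angle_deg: float, attempt: int = 1,
                  side: str = "right",
                  second_attempt_offset_deg: float = SECOND_ATTEMPT_OFFSET_DEG,
                  allow_nonstandard: bool = False,
                  offset_pivot: str = "entry",
                  entry_distance: float = ENTRY_DISTANCE,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Axis of one osteotomy attempt: ``(anchor point, unit direction)``.

    The direction lies in the reference plane and points from the
    posterolateral entry side toward the interspace target; the signed
    in-plane angle from the central (posterior) axis toward the approach
    side equals ``angle_deg`` for the first attempt and
    ``angle_deg + second_attempt_offset_deg`` for the second.

    The second attempt is rotated outward about the shared entry point
    (``offset_pivot='entry'``, the default), so the barrel sweeps a few
    millimetres laterally at the joint and removes residual articular
    bone; with ``offset_pivot='target'`` both attempts stay aimed at the
    interspace center instead.  The anchor is the target-depth point of
    the attempt (C itself for the first).
    """
    if not allow_nonstandard and angle_deg not in ALLOWED_ANGLES \
            and angle_deg != 0:
        raise ValueError(f"angle {angle_deg} not in {ALLOWED_ANGLES}")
    if attempt not in (1, 2):
        raise ValueError("attempt must be 1 or 2")
    if offset_pivot not in ("entry", "target"):
        raise ValueError("offset_pivot must be 'entry' or 'target'")
    sign = 1.0 if side == "right" else -1.0

    def in_plane_direction(total_deg: float) -> np.ndarray:
        theta = np.radians(total_deg)
        outward = (np.cos(theta) * frame.central_axis
                   + sign * np.sin(theta) * frame.lateral_axis)
        return -outward

    direction = in_plane_direction(
        angle_deg + (second_attempt_offset_deg if attempt == 2 else 0.0))
    if attempt == 1 or offset_pivot == "target":
        return frame.center.copy(), direction
    # pivot at the entry point of the first attempt
    entry = frame.center - entry_distance * in_plane_direction(angle_deg)
    anchor = entry + entry_distance * direction
    return anchor, direction


def trephine_cylinder(axis: tuple[np.ndarray, np.ndarray],
                      diameter_mm: float, length: float = 120.0,
                      entry_clearance: float = 60.0,
                      sections: int = 48,
                      allow_nonstandard: bool = False) -> ConvexSolid:
    """Convex solid of the trephine barrel on a planned axis.

    The barrel is a right prism with ``sections`` faces inscribed slightly
    outside the nominal circle so the polygonal volume equals the exact
    cylinder volume (mid-area radius correction); total length is
    ``length``, placed so it starts ``entry_clearance`` behind the target
    point C (beyond the posterior surface) and runs the rest past it.
    """
    if not allow_nonstandard and diameter_mm not in ALLOWED_DIAMETERS:
        raise ValueError(
            f"diameter {diameter_mm} not in {ALLOWED_DIAMETERS}; pass "
            f"allow_nonstandard=True to override")
    point, direction = axis
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # polygon with the same area as the circle: r_poly^2 * n/2 * sin(2pi/n)
    theta = 2.0 * np.pi / sections
    r_equal_area = (diameter_mm / 2.0) / np.sqrt(np.sinc(theta / np.pi))
    poly = r_equal_area * np.column_stack([
        np.cos(theta * np.arange(sections)),
        np.sin(theta * np.arange(sections))])
    # frame with local z along the axis
    zaxis = direction
    tmp = np.array([0.0, 0.0, 1.0])
    if abs(float(zaxis @ tmp)) > 0.99:
        tmp = np.array([1.0, 0.0, 0.0])
    xaxis = np.cross(tmp, zaxis)
    xaxis /= np.linalg.norm(xaxis)
    yaxis = np.cross(zaxis, xaxis)
    t = np.eye(4)
    t[:3, 0], t[:3, 1], t[:3, 2] = xaxis, yaxis, zaxis
    t[:3, 3] = point
    return ConvexSolid.from_extrusion(poly, -entry_clearance,
                                      length - entry_clearance, t,
                                      name=f"trephine_d{diameter_mm}")


def plan_tools(frame: InterspaceFrame, plan: TrephinePlan,
               sections: int = 48) -> list[ConvexSolid]:
    """Convex barrel solids for every attempt of a plan (1 or 2)."""
    plan.validate()
    tools = []
    for attempt in range(1, plan.attempts + 1):
        axis = trephine_axis(frame, plan.angle_deg, attempt, plan.side,
                             plan.second_attempt_offset_deg,
                             allow_nonstandard=plan.allow_nonstandard,
                             offset_pivot=plan.offset_pivot)
        tools.append(trephine_cylinder(
            axis, plan.diameter_mm, plan.cylinder_length,
            sections=sections, allow_nonstandard=plan.allow_nonstandard))
    return tools


def plan_frame(model: AnatomyModel, disc: str = "L4L5") -> InterspaceFrame:
    """Fit endplate planes and build the planning frame in one call."""
    cranial, caudal = disc[:2], disc[2:]
    upper = fit_endplate_plane(model, f"endplate_{cranial}_inferior")
    lower = fit_endplate_plane(model, f"endplate_{caudal}_superior")
    return build_interspace_frame(model, upper, lower, disc=disc)
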