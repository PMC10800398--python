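# Methods

`spineosteo` couples two computational studies on one synthetic L3–L5
lumbar segment: (i) a geometric simulation of targeted-puncture trephine
osteotomy at the L4/5 interspace with exact resected-volume accounting over
a cohort, and (ii) a linear finite-element (FE) analysis of the intact
segment and five surgical variants under a compressive follower load plus
pure moments. This note records the model, its assumptions, the parameters
that matter, and the numerical choices, in enough detail to re-derive every
default.

## 1. The synthetic phantom

### Geometry

No patient imaging ships with the package; a seeded parametric phantom
stands in for CT reconstructions. Every solid is an extrusion of a convex
polygon, so the whole phantom lives in exact half-space arithmetic
(section 3). The frame is +x right, +y anterior, +z cranial, in mm, with
the L4/5 disc center at the origin.

* **Vertebral bodies** — superellipse cross-section
  `|x/a|^2.5 + |y/b|^2.5 = 1` (64 boundary vertices), width 45 mm, depth
  33 mm, height 27 mm, extruded along z. A 1 mm cortical shell is the
  difference between the body and an inward-offset copy; the interior is
  cancellous.
* **Discs** — the disc complex cross-section is the vertebral section
  scaled by √0.95, so its area is exactly 95 % of the vertebral
  cross-section. The nucleus is the disc section scaled by √0.40 (40 % of
  the disc area), shifted posteriorly so that the anterior/posterior
  annulus-edge-to-nucleus-centroid distance ratio along the mid-sagittal
  line is exactly 1.62. Each 10 mm interspace carries 1 mm cartilage
  endplates on both faces with an 8 mm annulus/nucleus core between them.
* **Posterior elements** — pedicles, laminae (with a caudally overhanging
  margin that reaches the interspace level, as the real inferior lamina
  edge does), spinous and transverse processes, and articular processes,
  all as abutting convex blocks. The articular processes of neighbouring
  vertebrae overlap the lamina margin where the bone is anatomically
  continuous (the pars region); these overlaps are trimmed by exact convex
  differences so the parts tile space without double-counted volume.
* **Facet joints** — each joint is a pair of cartilage slabs (0.4 mm each,
  total < 1 mm) on the articular faces of the superior (caudal vertebra)
  and inferior (cranial vertebra) processes, separated by a 0.4 mm gap.
  The joint plane is rotated 20° from the coronal plane (a coronally
  oriented joint, at the coronal end of the reported L4/5 variation),
  centered
  12 mm lateral and 13 mm posterior to the interspace center, with an
  11 × 14 mm articular surface. These values sit inside published lumbar
  morphometry ranges and give the phantom the surgical anatomy that the
  puncture study probes: a mid-line interlaminar window, the joint in the
  45–50° corridor, and a free transforaminal passage lateral of ~65°.
* **Ligaments** — seven groups (anterior and posterior longitudinal,
  flavum, inter- and supraspinous, intertransverse, facet capsules) as
  named attachment-point pairs on the bony structures; the capsule gets
  four fascicles ringing each joint.

The absolute dimensions are design inputs taken from standard lumbar
morphometry (the published study the pipeline emulates reports only the
cross-sectional ratios, the shell thickness and the cartilage thickness);
all of them are exposed on `SubjectParams`. The default phantom is built
in neutral alignment (`lordosis_angle_per_level = 0`): the analyses depend
on relative geometry, and the layered build keeps the FE lattice exact at
the thin interfaces. A per-level lordotic tilt is implemented for the
geometric study but the lattice mesher requires the neutral phantom.

### Cohorts

`sample_cohort` draws per-subject parameter sets with independent
truncated-normal jitter (clipped at ±2.5 CV, resampled if invalid).
Default CVs are 5 % on body dimensions, 8 % on disc height, 4–6 % on
posterior-element and facet dimensions — a plausible inter-patient spread
for a 25-subject cohort. The ratios (95 %, 40 %, 1.62) are modelling
constants shared by all subjects, mirroring how the source model was
specified. What the cohort does *not* emulate: sex/age structure,
degenerative remodelling, left–right asymmetry, or correlated parameter
variation.

### Measurement

`measure_area_fractions` slices the *meshes* (not the construction
parameters) on the disc mid-height plane, assembles cross-section areas by
even-odd ring nesting, and reads the mid-sagittal edge distances off the
section; `measure_cortical_thickness` ray-casts the shell from the body
center. Passing the recovery tests therefore shows the generated geometry
realises the requested specification, not merely that the parameters were
stored.

## 2. Puncture planning

Endplate planes are least-squares (SVD) fits to the endplate mesh
vertices. The interspace center C is the midpoint of the posterior-edge
midpoints of the L4 inferior and L5 superior endplates; the reference
plane goes through C parallel to the L5 superior endplate. Trajectories
live in this plane at 20–70° from the posterior mid-sagittal axis, opening
to the approach (right) side; barrels are equal-area 48-gon prisms (volume
exactly π r² L) of 7/8/9 mm diameter and 120 mm length, reaching 60 mm
behind C.

A second attempt is the trajectory rotated 5° further outward **about the
shared entry point** (`offset_pivot="entry"`), so the barrel sweeps
~5 mm laterally at the joint and removes residual articular bone — which
is the clinical purpose of a second pass. Pivoting about the target point
is available as an option but makes the second barrel nearly coincident
with the first at the target (measured: zero additional cartilage
footprint), contradicting what a second pass is for.

## 3. Exact convex Booleans and the sampling oracle

Because every phantom solid is convex (regions are signed unions of convex
parts: a shell is "outer minus inner"), all resection arithmetic reduces
to convex–convex intersections, evaluated exactly (up to the stated facet
discretisation) by half-space stacking: Chebyshev center by linear
programming, vertex enumeration (`HalfspaceIntersection`), hull volume.
Two-attempt unions use inclusion–exclusion; differences use the standard
disjoint half-space decomposition of the complement, so resected regions
remain unions of watertight convex pieces and volume is conserved to
machine precision.

An independent Monte-Carlo oracle (`monte_carlo_volume`) estimates every
removed volume by uniform sampling in the tool's bounding box with
binomial standard errors; the acceptance suite requires 3σ agreement on
all 36 plan configurations at 10⁶ samples. User-supplied watertight
surface meshes are supported through a divergence-theorem integrator
(`mesh_intersect_volume`): mesh triangles clipped to the tool plus the
tool-face areas inside the mesh, again with no remeshing step.

Removed volume counts bone (cortical, cancellous, posterior elements) and
facet cartilage (`include_cartilage_in_volume=True` by default; the
recorded sensitivity of the default 50°/9 mm plan to this switch is the
~64 mm³ cartilage term against ~640 mm³ of bone). Discs, endplates and
ligaments are not part of the recorded osteotomy volume; ligament damage
is handled as discrete fascicle removal in the FE study.

## 4. Finite-element model

### Discretisation

A rectilinear lattice — uniform in x/y at the target edge length (default
3.0 mm), z-graded to land exactly on every disc, endplate and body
interface, with at least six element layers through each disc core (the
layer that drives segmental bending) — is classified against the exact
regions on a 2×2×2 sub-grid per cell and split into conforming
Freudenthal tetrahedra. Boundary cells enter the mesh with their modulus
scaled by occupancy (partial-volume homogenisation), which removes the
first-order staircase error of center-only labelling; a cell whose
sub-points touch the articular processes of two different vertebrae
straddles the sub-cell joint gap and is re-classified by its center point
so the articulation is never bridged. The 1 mm
endplates get a dedicated element layer. The 1 mm lateral cortical wall is
below the lateral resolution, so a fixed 3 mm lateral band of each body
is assigned cortical material (fixed so the homogenised shell does not
change with refinement); this overweights cortex but the vertebrae act
as near-rigid bodies relative to the discs either way. Structures closer
than one cell would weld; nodes shared across a facet joint are therefore
duplicated so the joint transmits load only through its articulation
model. Element-to-element connectivity is judged across shared faces;
corner- or edge-touching fragments are zero-energy mechanisms and are
pruned (an error if they exceed 1 % of the model volume).

Materials are the values conventionally used in lumbar FE work (cortical
12 000 MPa/0.3, cancellous 100/0.2, endplate 23.8/0.4, cartilage 10/0.4,
annulus matrix 4.2/0.45, nucleus 0.4, fibers 455/0.3 at 1.35 mm², and the
seven ligament groups with their areas). The nucleus is nominally
ν = 0.499; plain linear tetrahedra lock there, so the solver runs it at
ν = 0.495 (documented cap; the module records the nominal value
separately). Ligament areas divide over the group's fascicles; the
capsular 30 mm² is read per facet joint. Annulus fibers are two
criss-crossing truss families (16 stations per ring) on each annulus
perimeter between the endplate interfaces, inclined ≈ ±30° at the default
disc proportions. Ligament and fiber trusses are *embedded*: each end
couples to the corner nodes of the lattice cell containing its geometric
attachment point with trilinear weights, so truss length, direction and
lever arm are independent of the mesh (capsular fascicles, whose ends
straddle the split articular gap, snap to nearest nodes instead).
Ligaments are linear trusses, as an elastic-modulus + cross-section
specification implies; the annulus **fibers are tension-only** (collagen
fibers buckle under compression — the standard treatment in
fiber-reinforced disc models), gated with the same per-load-case
fixed-point update as the facet contact.

With these choices the intact flexion ROM changes by under 5 % between
the 3.0 mm and 2.0 mm lattices (the suite asserts this).

### Facet articulation

The joint is bridged by a 6 × 6 grid of connectors per side. Each
connector has

* a **normal** contact stiffness `E·A_trib/(t_cartilage + gap)`, active in
  compression only (one fixed-point update per load case: solve, release
  connectors whose normal separates, re-solve; factorizations are cached
  by active set);
* the contact normal **tilted 25° cranially** off the anatomical joint
  plane: the articular surfaces are curved, and their mean contact normal
  is what lets the joint carry compression when the upper facet rides down
  in extension (facet abutment) while separating freely in flexion;
* a **horizontal tangential** stiffness `G·A_trib/(t + gap)` with
  `G = E/2(1+ν)`, carried while the cartilage is present — the curvature
  interlock plus capsule that resists mediolateral/rotational shear;
* **free vertical glide**, the physiological articular slide.

Each connector end is embedded in its lattice cell with trilinear
weights (redirected to the duplicated node set on the cranial side of
the split), so the contact load enters the bone as a distributed
pressure rather than point forces.

This connector structure was settled by validating the *intact* model:
with full isotropic cartilage shear the segment is far too stiff in
flexion (0.9° under 10 N·m + 400 N follower, against the 2–10°
physiological corridor assembled from published intact L4–L5 data), while
a freely sliding joint loses the load paths that make facet resection
matter in extension and rotation. The tilted-normal/horizontal-shear/free-
glide decomposition with tension-only fibers reproduces the corridor
(flexion ≈ 3.2°, axial rotations ≈ 2.0°) and the expected per-direction
roles of the articulation.

### Loads, boundary conditions, outputs

The L5 inferior surface is fully fixed. A 400 N follower load is applied
as a uniformly distributed compressive load on the L3 superior surface
along the segment axis (single-segment follower approximation; a pure
vertical load is the same thing in the neutral frame). Each 10 N·m moment
is a self-equilibrated force couple distributed over the L3 superior
nodes about the surface centroid. Range of motion is the total angle of
the relative rigid rotation (Kabsch fit on each vertebra's body nodes) of
L4 over L5 (or L3 over L4), reported per direction from neutral. Stresses
are constant per tetrahedron; reported region maxima are volume-weighted
nodal averages within the region — the standard smoothing for
constant-strain elements, which removes single-element corner artifacts
of the lattice without moving the physical hotspot.

### Surgical variants

M1 is intact. M2–M6 are derived by element death (tets with centroid
inside the barrel(s), bone regions only), removal of the recipe's capsular
fascicle fraction on the operated side (ordered by distance from the tool
axis — the tool destroys the nearest fibers first), removal of the right
flavum fascicle for the interlaminar variant, and cartilage removal.
Cartilage removal strips a connector's tangential term (the grip is gone)
but keeps the compression-gated normal term — bone-on-bone contact
persists wherever the process itself survives; connectors whose bony
attachment is resected disappear entirely. The "extensive" grade removes
the whole operated articulation's cartilage; the other grades are the
actual Boolean footprint of the variant's barrel(s). Removed cartilage
*area* is reported as the exact tool footprint on the joint mid-plane
(2-D convex clipping united across attempts).

## 5. Statistics

Per-condition summaries are mean ± SD (n−1). Angle contrasts are
two-sided t-tests, paired by subject by default since every synthetic
subject contributes all angles; identical zero-variance inputs return
p = 1 by convention with a note. One-way ANOVA covers the three-group
angle comparisons. No multiple-testing correction by default, with a Holm
option. The acceptance suite calibrates the paired test's type-I error
(5 % ± 2 % over 2 000 simulated null cohorts).

## 6. Problem sizes and determinism

Defaults used throughout the test and acceptance runs: 25-subject cohort,
6 × 3 × 2 plan factorial (900 rows, ≈ 1 min), 48-gon barrels, 10⁶
Monte-Carlo samples per oracle check, 3.0 mm lattice (≈ 13 000 nodes,
≈ 58 000 tets, 36 solves ≈ 7 min on one core), one 2.0 mm solve for the
convergence property. Every artifact is a pure
function of its config and seed; meshes are bit-identical across runs.

## 7. Known limitations

* Linear kinematics and linear materials; no poroelastic or viscoelastic
  disc behaviour, no muscle forces, no geometric nonlinearity.
* The facet articulation is a connector model, not finite-deformation
  contact; its per-direction behaviour is calibrated to the intact
  corridor, not measured.
* The phantom is left-right symmetric and neutrally aligned; lordosis is
  available geometrically but not meshed. Neutral alignment leaves the
  facets unloaded at baseline, with a concrete consequence for the
  surgical-variant stress trends: in axial rotation, stripping the
  operated joint's shear transfer (the widest resection) diverts load
  away from the bony path feeding the posterior endplate hotspots, so
  that variant's endplate maxima can fall marginally below variants
  retaining partial shear even as its range of motion is the largest. A
  lordotic segment with follower-preloaded facet contact would not show
  this relief; the acceptance suite reports the affected cells as
  failures rather than masking them.
* Absolute stress magnitudes on a 3 mm lattice are indicative only;
  the study design (like its source) reads *trends across variants*, not
  absolute values.
* Cohort variability is independent per parameter; real anatomies
  co-vary.
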