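# spineosteo

Simulation pipeline for **targeted-puncture trephine osteotomy at the
L4/5 intervertebral space** and its biomechanical consequences, built for
spine-biomechanics researchers and surgical planners who want the two
halves of that question in one reproducible package:

1. **How much bone does each approach remove?** Percutaneous endoscopic
   lumbar discectomy reaches the disc either through the interlaminar
   window (PEID, entry angles 20–40° from the mid-sagittal axis) or
   through the foramen (PTED, 50–70°), cutting an access channel with a
   7–9 mm trephine in one or two passes. The package plans those
   trajectories on a parametric L3–L5 phantom and computes the resected
   bone-and-cartilage volume `V = vol(bone ∩ (C₁ ∪ C₂))` by exact convex
   Boolean intersection, over a jittered cohort of synthetic subjects,
   with a Monte-Carlo point-sampling oracle cross-checking every number.

2. **What does the resection do to segmental stability?** Six
   finite-element models — intact (M1) plus five surgical variants
   (M2: 8 mm/60°; M3: 8 mm/30° with right flavum removal; M4: 8 mm/50°;
   M5: 8 mm/50°, two passes; M6: 9 mm/50° with extensive facet-cartilage
   and ¾ capsule removal) — are solved under a 400 N follower load plus
   10 N·m pure moments in six directions. Outputs are the L4–L5 range of
   motion (ROM, the relative rigid rotation of L4 over L5 fitted per
   vertebra) and the maximum von Mises stress on the L4/5 annulus and on
   the adjacent endplates.

The phantom reproduces, as *measured* properties of its meshes, the
geometric specification such models are built to: a ~1 mm cortical shell,
a disc complex occupying ~95 % of the vertebral cross-section, a nucleus
at 40 % of the disc area, an anterior/posterior annulus-edge-to-nucleus
distance ratio of 1.62, and facet cartilage thinner than 1 mm.

## Worked example

```python
from spineosteo import (SubjectParams, generate_phantom,
                        measure_area_fractions, TrephinePlan,
                        plan_frame, plan_tools, intersect_volume,
                        monte_carlo_volume)

model = generate_phantom(SubjectParams(rng_seed=42))
print(measure_area_fractions(model))
# {'nucleus_over_disc': 0.4000000000000001,
#  'disc_over_vertebra': 0.9499999999999996,
#  'ap_offset_ratio': 1.6200000000000094}

frame = plan_frame(model)                     # L4/5 interspace frame
plan = TrephinePlan(angle_deg=50, diameter_mm=9, attempts=1)
tools = plan_tools(frame, plan)
total, breakdown, _ = intersect_volume(model, tools)
print(round(total, 1))                        # 702.6  (mm^3 removed)
print({k: round(v, 1) for k, v in breakdown.items()})
# {'lamina': 3.0, 'facet_L4_inferior': 109.2,
#  'facet_L5_superior': 526.6, 'cartilage': 63.7, 'other': 0.0}

mc = monte_carlo_volume(model, tools, n_samples=10**6, seed=1)
print(round(mc['estimate'], 1), round(mc['stderr'], 2))
# 710.7 7.22   -- the sampling oracle agrees within 1.2 standard errors
```

The numbers say: a single 9 mm pass at 50° removes ~0.7 cm³, three
quarters of it from the superior articular process of L5 with the rest
from the L4 inferior process and the joint cartilage — exactly why the
transforaminal 50° corridor is the structurally expensive one, and why
the cohort-level volume curves peak there before falling off toward the
foramen at 70°.

The cohort and FE studies run from the command line:

```bash
spineosteo volumes --out runs/volumes --seed 0          # 900-row cohort table + stats
spineosteo biomech --out runs/biomech --seed 0          # 36-cell ROM/stress table
spineosteo validate --out runs/validate                 # analytic verification suite
```

`runs/volumes/summary.csv` holds the mean ± SD resected volume per
(group, angle, diameter, attempts) condition and `contrasts.csv` the
paired angle comparisons with the usual `*`/`**` flags;
`runs/biomech/fe_results.csv` holds one row per variant × direction with
ROM and per-region stress maxima, rendered as tables in `report.md`.

## Layout

| module | role |
|---|---|
| `spineosteo.convex` | exact convex half-space solids and Booleans |
| `spineosteo.anatomy` | parametric phantom, cohorts, spec measurement |
| `spineosteo.planner` | endplate planes, interspace frame, trephine axes/barrels |
| `spineosteo.osteotomy` | resected volumes, Monte-Carlo oracle, resected models |
| `spineosteo.fe` | lattice tet meshing, ligaments/facet connectors, sparse solver, variant protocol |
| `spineosteo.stats` | cohort summaries, paired t-tests, ANOVA |
| `spineosteo.cli` | `volumes` / `biomech` / `validate` subcommands |

Methodological details — model assumptions, parameter provenance, the
facet articulation model, numerical choices and known limitations — are
in [`docs/methods.md`](docs/methods.md).
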