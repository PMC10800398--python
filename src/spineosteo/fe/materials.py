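"""Material cards for the lumbar segment model.

Linear elastic constants follow the values conventionally used in lumbar
finite-element studies (cortical/cancellous bone, cartilage endplates,
fiber-reinforced annulus, near-incompressible nucleus, and seven ligament
groups with their cross-sectional areas in mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialCard:
    name: str
    young_modulus: float          # MPa
    poisson_ratio: float
    cross_sectional_area: float | None = None   # mm^2, truss materials only

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError(f"{self.name}: Young's modulus must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"{self.name}: Poisson ratio must be in [0, 0.5)")
        if self.cross_sectional_area is not None \
                and self.cross_sectional_area <= 0:
            raise ValueError(f"{self.name}: area must be > 0")


#: Nucleus Poisson ratio is nominally 0.499; plain linear tetrahedra lock at
#: that value, so the solver caps it (documented flag in the solver config).
NUCLEUS_NOMINAL_POISSON = 0.499

MATERIALS: dict[str, MaterialCard] = {
    "cortical": MaterialCard("cortical", 12000.0, 0.3),
    "cancellous": MaterialCard("cancellous", 100.0, 0.2),
    "endplate": MaterialCard("endplate", 23.8, 0.4),
    "cartilage": MaterialCard("cartilage", 10.0, 0.4),
    "annulus_matrix": MaterialCard("annulus_matrix", 4.2, 0.45),
    "nucleus": MaterialCard("nucleus", 0.4, 0.495),  # capped from 0.499
    "annulus_fiber": MaterialCard("annulus_fiber", 455.0, 0.3, 1.35),
    "ALL": MaterialCard("ALL", 7.8, 0.3, 63.7),
    "PLL": MaterialCard("PLL", 10.0, 0.3, 20.0),
    "LF": MaterialCard("LF", 15.0, 0.3, 40.0),
    "ISL": MaterialCard("ISL", 10.0, 0.3, 40.0),
    "SSL": MaterialCard("SSL", 8.0, 0.3, 30.0),
    "ITL": MaterialCard("ITL", 10.0, 0.3, 1.8),
    "CL": MaterialCard("CL", 7.5, 0.3, 30.0),
}

#: number of truss fascicles each ligament group's area is divided over.
#: Midline ligaments are one fascicle per level; LF and ITL are paired
#: left/right.  The capsular area is per facet joint (each joint has its
#: own capsule), divided over its four fascicles.
FASCICLES_PER_LEVEL = {
    "ALL": 1, "PLL": 1, "LF": 2, "ISL": 1, "SSL": 1, "ITL": 2, "CL": 4,
}

#: anatomy region prefix -> material name for the solid mesh
REGION_MATERIAL = {
    "cortical": "cortical",
    "cancellous": "cancellous",
    "posterior_elements": "cortical",
    "annulus": "annulus_matrix",
    "nucleus": "nucleus",
    "endplate": "endplate",
}


def material_for_region(region_name: str) -> MaterialCard:
    for suffix, mat in REGION_MATERIAL.items():
        if suffix in region_name:
            return MATERIALS[mat]
    raise KeyError(f"no material mapping for region {region_name!r}")
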