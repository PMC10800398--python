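"""Serialization: meshes (STL/PLY), landmarks (JSON), configs (YAML), VTU.

The VTU writer emits a minimal ASCII XML unstructured grid (tetra cells
with point displacements and cell von Mises stress), readable by ParaView.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .anatomy import AnatomyModel, CohortSpec, SubjectParams


def export_model(model: AnatomyModel, out_dir: str | Path,
                 subject: str = "subject", fmt: str = "stl") -> list[Path]:
    """Write every regional mesh as ``<subject>_<region>.<fmt>`` + landmarks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in model.regions:
        path = out_dir / f"{subject}_{name}.{fmt}"
        model.region_mesh(name).export(path)
        written.append(path)
    lm_path = out_dir / f"{subject}_landmarks.json"
    with open(lm_path, "w") as fh:
        json.dump({k: np.asarray(v).tolist()
                   for k, v in model.landmarks.items()}, fh, indent=1)
    written.append(lm_path)
    return written


def params_to_yaml(params: SubjectParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)


def params_from_yaml(path: str | Path) -> SubjectParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SubjectParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown subject parameters: {sorted(unknown)}")
    return SubjectParams(**data)


def cohort_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    data = dataclasses.asdict(spec)
    if data.get("base_params") is not None:
        data["base_params"] = dataclasses.asdict(spec.base_params)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def provenance(config: dict, seed: int, path: str | Path) -> None:
    """Record the exact run recipe: config hash, seed, package versions."""
    import scipy
    import trimesh

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "spineosteo": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "trimesh": trimesh.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, default=str)


def write_vtu(path: str | Path, nodes: np.ndarray, tets: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """ASCII XML VTU (tetra unstructured grid) with optional fields."""
    nodes = np.asarray(nodes, float)
    tets = np.asarray(tets, np.int64)
    n_pts, n_cells = len(nodes), len(tets)

    def arr(a, fmt="%.9g"):
        return "\n".join(" ".join(fmt % x for x in np.atleast_1d(row))
                         for row in a)

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(nodes), "</DataArray>", "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(tets, "%d"), "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(4 * np.arange(1, n_cells + 1)[:, None], "%d"), "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full((n_cells, 1), 10), "%d"), "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, data in point_data.items():
            data = np.asarray(data, float)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            parts += [f'<DataArray type="Float64" Name="{name}" '
                      f'NumberOfComponents="{ncomp}" format="ascii">',
                      arr(data.reshape(n_pts, -1)), "</DataArray>"]
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, data in cell_data.items():
            data = np.asarray(data, float)
            parts += [f'<DataArray type="Float64" Name="{name}" '
                      f'NumberOfComponents="1" format="ascii">',
                      arr(data.reshape(n_cells, -1)), "</DataArray>"]
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))
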