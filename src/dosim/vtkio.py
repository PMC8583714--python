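"""Legacy-ASCII VTK output of mesh and per-element fields.

One unstructured-grid file per snapshot; the axisymmetric (r, z) plane is
written as z=0 quads with region and tissue fields attached as cell data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk"]


def write_vtk(path, mesh: Mesh, cell_data: dict[str, np.ndarray] | None = None,
              title: str = "dosim snapshot") -> None:
    """Write the mesh and optional per-element scalar fields to ``path``."""
    cell_data = cell_data or {}
    for name, arr in cell_data.items():
        if np.asarray(arr).shape[0] != mesh.n_elements:
            raise ValueError(f"cell field {name!r} not defined per element")
    lines = [
        "# vtk DataFile Version 3.0",
        title[:255],
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    for quad in mesh.elements:
        lines.append("4 " + " ".join(str(int(i)) for i in quad))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["9"] * mesh.n_elements)  # VTK_QUAD
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(x)) for x in mesh.region)
    for name, arr in cell_data.items():
        safe = name.replace(" ", "_")
        lines.append(f"SCALARS {safe} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(x):.9g}" for x in np.asarray(arr))
    Path(path).write_text("\n".join(lines) + "\n")
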