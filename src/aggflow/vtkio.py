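"""Minimal legacy-ASCII VTK output for cell-centered lattices.

Fields are written as STRUCTURED_POINTS point data sampled at the flow-grid
cell centers, one file per run with any number of scalar fields.  The
legacy ASCII format is universally readable (ParaView, VisIt, pyvista) and
keeps the artifact free of binary output.
"""

from __future__ import annotations

import numpy as np

from .imaging import VoxelGrid

__all__ = ["write_structured_points"]


def write_structured_points(path, grid: VoxelGrid, fields: dict) -> None:
    """Write scalar lattices (shape = grid.shape) to one legacy VTK file."""
    nx, ny, nz = grid.shape
    h = grid.h
    ox, oy, oz = (grid.origin[i] + 0.5 * h for i in range(3))
    lines = [
        "# vtk DataFile Version 3.0",
        "aggflow cell-centered fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {ox:.9g} {oy:.9g} {oz:.9g}",
        f"SPACING {h:.9g} {h:.9g} {h:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    chunks = ["\n".join(lines)]
    for name, data in fields.items():
        arr = np.asarray(data, dtype=float)
        if arr.shape != grid.shape:
            raise ValueError(f"field '{name}' shape {arr.shape} != grid {grid.shape}")
        chunks.append(f"\nSCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest; our arrays are [x, y, z]
        flat = arr.transpose(2, 1, 0).ravel()
        chunks.append("\n".join(f"{v:.7g}" for v in flat))
    with open(path, "w") as fh:
        fh.write("".join(chunks) + "\n")
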