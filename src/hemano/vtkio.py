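"""Minimal legacy-ASCII VTK writer for structured quadrilateral meshes.

Writes DATASET UNSTRUCTURED_GRID files (VTK_QUAD cells) with optional
point and cell data, sufficient for ParaView/VisIt inspection of meshes and
fields.  Only the small legacy text dialect is produced.
"""

from __future__ import annotations

import numpy as np

VTK_QUAD = 9


def write_quad_mesh(path, Z, Y, point_data=None, cell_data=None, title="hemano"):
    """Write an (ni, nj) structured grid of nodes as legacy VTK quads.

    ``Z``/``Y`` are node coordinate arrays; ``point_data`` maps names to
    (ni, nj) arrays; ``cell_data`` maps names to (ni-1, nj-1) arrays (numeric
    or string labels, which are encoded as integer codes).
    """
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ni, nj = Z.shape
    npts = ni * nj
    ncell = (ni - 1) * (nj - 1)

    def pid(i, j):
        return i * nj + j

    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {npts} double",
    ]
    for i in range(ni):
        for j in range(nj):
            lines.append(f"{Z[i, j]:.9e} {Y[i, j]:.9e} 0.0")
    lines.append(f"CELLS {ncell} {5 * ncell}")
    for i in range(ni - 1):
        for j in range(nj - 1):
            lines.append(
                f"4 {pid(i, j)} {pid(i + 1, j)} {pid(i + 1, j + 1)} {pid(i, j + 1)}"
            )
    lines.append(f"CELL_TYPES {ncell}")
    lines.extend([str(VTK_QUAD)] * ncell)

    def scalars(name, arr):
        out = [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out.extend(f"{v:.9e}" for v in np.asarray(arr, dtype=float).ravel())
        return out

    if point_data:
        lines.append(f"POINT_DATA {npts}")
        for name, arr in point_data.items():
            lines.extend(scalars(name, arr))
    if cell_data:
        lines.append(f"CELL_DATA {ncell}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "OUS":  # label field -> integer codes
                labels = sorted(set(arr.ravel().tolist()))
                codes = np.array(
                    [[labels.index(v) for v in row] for row in arr], dtype=float
                )
                lines.extend(scalars(name, codes))
            else:
                lines.extend(scalars(name, arr))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_mesh(path, mesh, extra_cell_data=None):
    """Export a :class:`~hemano.geometry.Mesh` with its domain labels."""
    Zn, Yn = mesh.node_coords()
    cd = {"domain": mesh.cell_domain()}
    if extra_cell_data:
        cd.update(extra_cell_data)
    write_quad_mesh(path, Zn, Yn, cell_data=cd)
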