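"""Minimal legacy-ASCII VTK writers for inspection in standard viewers.

Covers exactly what the package produces: a labeled voxel image
(STRUCTURED_POINTS) and a hexahedral mesh with optional point/cell data
(UNSTRUCTURED_GRID, cell type 12).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_voxel_model", "write_hexmesh"]


def write_voxel_model(path, model) -> Path:
    """Write a LabeledVoxelModel as VTK structured points with a 'label' field."""
    path = Path(path)
    nx, ny, nz = model.shape
    h = model.voxel_size
    labels = model.labels  # [i, j, k]; VTK wants x fastest
    flat = labels.transpose(2, 1, 0).ravel()
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncervifem voxel model\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {model.origin[0]} {model.origin[1]} {model.origin[2]}\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS label int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in flat))
        fh.write("\n")
    return path


def write_hexmesh(path, mesh, point_data: dict | None = None,
                  cell_data: dict | None = None) -> Path:
    """Write a HexMesh (plus optional fields) as a VTK unstructured grid.

    ``point_data`` values may be (N,) scalars or (N, 3) vectors; ``cell_data``
    values are (E,) scalars.
    """
    path = Path(path)
    n, e = mesh.n_nodes, mesh.n_elements
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncervifem hex mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, mesh.nodes, fmt="%.6g")
        fh.write(f"CELLS {e} {e * 9}\n")
        cells = np.hstack([np.full((e, 1), 8, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {e}\n")
        fh.write("\n".join(["12"] * e))
        fh.write("\n")
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} float\n")
                    np.savetxt(fh, arr, fmt="%.6g")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.ravel()[:, None], fmt="%.6g")
        if cell_data:
            fh.write(f"CELL_DATA {e}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr).ravel()[:, None], fmt="%.6g")
    return path
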