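"""Minimal ASCII VTU (VTK XML UnstructuredGrid) writer for solution export.

Writes nodes, tetrahedral connectivity, nodal point data (e.g. the potential
V) and per-cell data (region tags, |E|, activation masks), readable by
ParaView and other standard VTK tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtu"]

_VTK_TETRA = 10


def _array_block(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data)
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    if np.issubdtype(data.dtype, np.integer):
        dtype, fmt = "Int32", "%d"
    else:
        dtype, fmt = "Float64", "%.10g"
    flat = data.reshape(-1)
    body = "\n".join(
        indent + " ".join(fmt % v for v in flat[i : i + 6]) for i in range(0, len(flat), 6)
    )
    return (
        f'{indent}<DataArray type="{dtype}" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n{indent}</DataArray>\n'
    )


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh with optional nodal/per-tet arrays; returns the path."""
    path = Path(path)
    point_data = point_data or {}
    cell_data = {"region": mesh.region.astype(np.int32), **(cell_data or {})}
    n_pts, n_cells = mesh.n_nodes, mesh.n_tets
    ind = "        "
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write("  <UnstructuredGrid>\n")
        fh.write(f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n')
        fh.write("      <Points>\n")
        fh.write(_array_block("Points", mesh.nodes, ind))
        fh.write("      </Points>\n")
        fh.write("      <Cells>\n")
        fh.write(_array_block("connectivity", mesh.tets.astype(np.int32), ind))
        fh.write(_array_block("offsets", np.arange(4, 4 * n_cells + 1, 4, dtype=np.int32), ind))
        fh.write(_array_block("types", np.full(n_cells, _VTK_TETRA, dtype=np.int32), ind))
        fh.write("      </Cells>\n")
        if point_data:
            fh.write("      <PointData>\n")
            for name, arr in point_data.items():
                fh.write(_array_block(name, arr, ind))
            fh.write("      </PointData>\n")
        fh.write("      <CellData>\n")
        for name, arr in cell_data.items():
            fh.write(_array_block(name, arr, ind))
        fh.write("      </CellData>\n")
        fh.write("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    return path
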