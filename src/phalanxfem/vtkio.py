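"""Minimal ASCII VTK XML (.vtu) and STL writers for tet10 meshes.

Only what the pipeline needs to dump meshes and per-step fields for
inspection in ParaView: UnstructuredGrid with quadratic tetra cells
(VTK type 24), point data and cell data, plus a surface STL of the
boundary faces (corner triangles).
"""

from __future__ import annotations

import numpy as np

VTK_QUADRATIC_TETRA = 24


def _ascii(arr, fmt="%.9g"):
    return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row)) for row in arr)


def write_vtu(mesh, path, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Write a tet10 mesh with optional nodal/element fields."""
    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.elements, fmt="%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii((10 * np.arange(1, m + 1))[:, None], fmt="%d"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full((m, 1), VTK_QUADRATIC_TETRA), fmt="%d"),
        "</DataArray>",
        "</Cells>",
    ]

    def data_block(tag, fields):
        parts.append(f"<{tag}>")
        for name, arr in (fields or {}).items():
            arr = np.asarray(arr, dtype=float)
            comps = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{comps}" format="ascii">'
            )
            parts.append(_ascii(arr if arr.ndim > 1 else arr[:, None]))
            parts.append("</DataArray>")
        parts.append(f"</{tag}>")

    data_block("PointData", point_data)
    data_block("CellData", cell_data)
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_stl(mesh, path, name: str = "surface") -> None:
    """ASCII STL of the boundary surface (corner-node triangles)."""
    from .fem.mesh import boundary_faces

    faces = boundary_faces(mesh)[:, :3]
    tri = mesh.nodes[faces]
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(nrm, axis=1)
    nrm = nrm / np.where(lens > 0, lens, 1.0)[:, None]
    lines = [f"solid {name}"]
    for f, nv in zip(tri, nrm):
        lines.append(f"facet normal {nv[0]:.6e} {nv[1]:.6e} {nv[2]:.6e}")
        lines.append("outer loop")
        for v in f:
            lines.append(f"vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}")
        lines.append("endloop")
        lines.append("endfacet")
    lines.append(f"endsolid {name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
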