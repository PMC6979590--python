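"""Mesh and field I/O: VTU (XML ascii) write/read, Gmsh MSH and legacy VTK read.

Only the small text subset the benchmarks need is supported: 3D points,
tet4/hex8 connectivity, and per-node / per-cell float fields.  Files are
plain ascii so results stay diffable and loadable by standard VTK viewers.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .elements import HEX8, TET4, nodes_per_cell
from .mesh import Mesh, _finish_mesh

__all__ = ["write_vtu", "read_vtu", "read_mesh", "FieldAssociationError", "MeshIOError"]

VTK_CELL_TYPE = {TET4: 10, HEX8: 12}
CELL_TYPE_FROM_VTK = {10: TET4, 12: HEX8}
GMSH_CELL_TYPE = {4: TET4, 5: HEX8}


class MeshIOError(IOError):
    """Malformed or unsupported mesh file."""


class FieldAssociationError(ValueError):
    """Field length matches neither the node nor the cell count."""


def _split_fields(mesh: Mesh, fields: dict):
    point_data, cell_data = {}, {}
    for name, values in (fields or {}).items():
        arr = np.asarray(values, dtype=float)
        if len(arr) == mesh.n_nodes and mesh.n_nodes != mesh.n_cells:
            point_data[name] = arr
        elif len(arr) == mesh.n_cells:
            cell_data[name] = arr
        elif len(arr) == mesh.n_nodes:
            point_data[name] = arr
        else:
            raise FieldAssociationError(
                f"field {name!r} has length {len(arr)}; mesh has "
                f"{mesh.n_nodes} nodes and {mesh.n_cells} cells"
            )
    return point_data, cell_data


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr, dtype=float).ravel()
    return " ".join(f"{v:.17g}" for v in flat)


def write_vtu(mesh: Mesh, fields: dict | None, path, config: str = "cur") -> None:
    """Write the mesh and optional fields as an ascii VTU file.

    Fields are associated by length: per-node arrays become PointData
    (components flattened), per-cell arrays CellData.  ``config`` selects
    the coordinates written ("cur" or "ref").
    """
    point_data, cell_data = _split_fields(mesh, fields)
    coords = mesh.cur_coords if config == "cur" else mesh.ref_coords
    nn = nodes_per_cell(mesh.cell_type)
    lines = []
    w = lines.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("  <UnstructuredGrid>")
    w(f'    <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_cells}">')
    w("      <Points>")
    w('        <DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w("          " + _fmt(coords))
    w("        </DataArray>")
    w("      </Points>")
    w("      <Cells>")
    w('        <DataArray type="Int64" Name="connectivity" format="ascii">')
    w("          " + " ".join(str(int(v)) for v in mesh.cells.ravel()))
    w("        </DataArray>")
    w('        <DataArray type="Int64" Name="offsets" format="ascii">')
    w("          " + " ".join(str(nn * (i + 1)) for i in range(mesh.n_cells)))
    w("        </DataArray>")
    w('        <DataArray type="UInt8" Name="types" format="ascii">')
    w("          " + " ".join([str(VTK_CELL_TYPE[mesh.cell_type])] * mesh.n_cells))
    w("        </DataArray>")
    w("      </Cells>")
    for tagname, data in (("PointData", point_data), ("CellData", cell_data)):
        w(f"      <{tagname}>")
        for name, arr in data.items():
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            w(f'        <DataArray type="Float64" Name="{name}" '
              f'NumberOfComponents="{ncomp}" format="ascii">')
            w("          " + _fmt(arr))
            w("        </DataArray>")
        w(f"      </{tagname}>")
    w("    </Piece>")
    w("  </UnstructuredGrid>")
    w("</VTKFile>")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtu(path):
    """Read an ascii VTU written by :func:`write_vtu`.

    Returns ``(mesh, fields)``; the mesh boundary is re-tagged generically
    as ``boundary`` (tags are not stored in VTU).
    """
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise MeshIOError(f"{path}: malformed XML ({exc})") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no UnstructuredGrid Piece found")
    pts = piece.find("./Points/DataArray")
    coords = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("./Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    offsets = np.fromstring(arrays["offsets"].text, sep=" ", dtype=np.int64)
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=np.int64)
    vtk_types = set(int(t) for t in types)
    if len(vtk_types) != 1 or vtk_types.pop() not in CELL_TYPE_FROM_VTK:
        raise MeshIOError(f"{path}: unsupported or mixed VTK cell types {sorted(set(types))}")
    cell_type = CELL_TYPE_FROM_VTK[int(types[0])]
    nn = nodes_per_cell(cell_type)
    if np.any(np.diff(np.concatenate([[0], offsets])) != nn):
        raise MeshIOError(f"{path}: ragged connectivity offsets")
    cells = conn.reshape(-1, nn)
    fields = {}
    for section in ("PointData", "CellData"):
        sec = piece.find(f"./{section}")
        if sec is None:
            continue
        for da in sec.findall("./DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            fields[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    mesh = Mesh(ref_coords=coords, cells=cells, cell_type=cell_type)
    mesh = _finish_mesh(mesh, lambda fc: "boundary")
    return mesh, fields


# -- Gmsh MSH ------------------------------------------------------------

def _read_msh2(lines, path):
    it = iter(lines)
    coords, cells, ctype = None, [], None
    for line in it:
        if line.startswith("$Nodes"):
            n = int(next(it))
            data = np.array([next(it).split() for _ in range(n)], dtype=float)
            order = np.argsort(data[:, 0])
            renum = {int(data[i, 0]): r for r, i in enumerate(order)}
            coords = data[order, 1:4]
        elif line.startswith("$Elements"):
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                if etype not in GMSH_CELL_TYPE:
                    continue
                ntags = int(parts[2])
                conn = [renum[int(v)] for v in parts[3 + ntags:]]
                this = GMSH_CELL_TYPE[etype]
                if ctype is None:
                    ctype = this
                elif ctype != this:
                    raise MeshIOError(f"{path}: mixed volume cell types")
                cells.append(conn)
    if coords is None or not cells:
        raise MeshIOError(f"{path}: no nodes or no volume elements found")
    return coords, np.array(cells, dtype=np.int64), ctype


def _read_msh4(lines, path):
    it = iter(lines)
    coords = None
    renum = {}
    cells, ctype = [], None
    for line in it:
        if line.startswith("$Nodes"):
            nblocks, ntot = (int(v) for v in next(it).split()[:2])
            coords = np.empty((ntot, 3))
            row = 0
            for _ in range(nblocks):
                nb = int(next(it).split()[3])
                tags = [int(next(it)) for _ in range(nb)]
                for t in tags:
                    renum[t] = row
                    coords[row] = [float(v) for v in next(it).split()[:3]]
                    row += 1
        elif line.startswith("$Elements"):
            nblocks = int(next(it).split()[0])
            for _ in range(nblocks):
                hdr = next(it).split()
                etype, nb = int(hdr[2]), int(hdr[3])
                for _ in range(nb):
                    parts = next(it).split()
                    if etype in GMSH_CELL_TYPE:
                        this = GMSH_CELL_TYPE[etype]
                        if ctype is None:
                            ctype = this
                        elif ctype != this:
                            raise MeshIOError(f"{path}: mixed volume cell types")
                        cells.append([renum[int(v)] for v in parts[1:]])
    if coords is None or not cells:
        raise MeshIOError(f"{path}: no nodes or no volume elements found")
    return coords, np.array(cells, dtype=np.int64), ctype


def _read_msh(path):
    lines = Path(path).read_text().splitlines()
    try:
        fmt_idx = lines.index("$MeshFormat")
        version = float(lines[fmt_idx + 1].split()[0])
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"{path}: missing $MeshFormat section") from exc
    if version >= 4.0:
        return _read_msh4(lines, path)
    if version >= 2.0:
        return _read_msh2(lines, path)
    raise MeshIOError(f"{path}: unsupported MSH version {version}")


def _read_legacy_vtk(path):
    lines = [ln for ln in Path(path).read_text().splitlines()]
    coords, cells, ctype = None, None, None
    i = 0
    while i < len(lines):
        ln = lines[i].split()
        if ln and ln[0] == "POINTS":
            n = int(ln[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            coords = np.array(vals).reshape(n, 3)
            continue
        if ln and ln[0] == "CELLS":
            n = int(ln[1])
            vals = []
            i += 1
            while len(vals) < int(ln[2]):
                vals.extend(int(v) for v in lines[i].split())
                i += 1
            rows, j = [], 0
            for _ in range(n):
                cnt = vals[j]
                rows.append(vals[j + 1: j + 1 + cnt])
                j += cnt + 1
            cells = rows
            continue
        if ln and ln[0] == "CELL_TYPES":
            n = int(ln[1])
            vals = []
            i += 1
            while len(vals) < n:
                vals.extend(int(v) for v in lines[i].split())
                i += 1
            tset = set(vals)
            if len(tset) != 1 or vals[0] not in CELL_TYPE_FROM_VTK:
                raise MeshIOError(f"{path}: unsupported VTK cell types {sorted(tset)}")
            ctype = CELL_TYPE_FROM_VTK[vals[0]]
            continue
        i += 1
    if coords is None or cells is None or ctype is None:
        raise MeshIOError(f"{path}: incomplete legacy VTK file")
    return coords, np.array(cells, dtype=np.int64), ctype


def read_mesh(path) -> Mesh:
    """Read a mesh from Gmsh MSH (v2.2/v4.1), legacy VTK, or VTU.

    The boundary is tagged ``boundary``; re-tag facets for specific
    problems after loading.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"{path}: no such file")
    suffix = path.suffix.lower()
    if suffix == ".vtu":
        return read_vtu(path)[0]
    if suffix == ".msh":
        coords, cells, ctype = _read_msh(path)
    elif suffix == ".vtk":
        coords, cells, ctype = _read_legacy_vtk(path)
    else:
        raise MeshIOError(f"{path}: unsupported mesh format {suffix!r}")
    mesh = Mesh(ref_coords=coords, cells=cells, cell_type=ctype)
    return _finish_mesh(mesh, lambda fc: "boundary")
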