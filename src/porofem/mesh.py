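"""Structured meshes for the poroelastic benchmarks.

Provides hexahedral boxes/columns, an extruded tetrahedral cylinder, a
conforming hex-to-tet splitter, and the connectivity the stabilized method
needs: the interior-face list (for the pressure-jump term) and tagged
boundary facets (for boundary conditions and flux multipliers).

Conventions: 0-based node and cell indices; facet vertex rings follow the
outward-normal right-hand rule in the reference configuration; each interior
face is stored once with ``left cell < right cell`` and the jump sign fixed
as (left value - right value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements
from .elements import HEX8, TET4, local_facets, nodes_per_cell

__all__ = [
    "Mesh",
    "TopologyError",
    "MeshQualityError",
    "build_box_hex_mesh",
    "build_cylinder_tet_mesh",
    "tetrahedralize",
    "extract_interior_faces",
]


class TopologyError(ValueError):
    """Non-conforming connectivity (a face shared by more than two cells)."""


class MeshQualityError(ValueError):
    """Degenerate or inverted cells."""


@dataclass
class Mesh:
    """Unstructured conforming mesh of one cell type.

    boundary_facets : list of ``(cell, local_facet, nodes, tag)``
    interior_faces  : list of ``(left_cell, right_cell, nodes)`` with
                      ``left_cell < right_cell``
    node_sets       : named node-index arrays (e.g. the cylinder axis)
    """

    ref_coords: np.ndarray
    cells: np.ndarray
    cell_type: str
    cur_coords: np.ndarray = None
    boundary_facets: list = field(default_factory=list)
    interior_faces: list = field(default_factory=list)
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ref_coords = np.ascontiguousarray(self.ref_coords, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        if self.cur_coords is None:
            self.cur_coords = self.ref_coords.copy()
        else:
            self.cur_coords = np.ascontiguousarray(self.cur_coords, dtype=float)
        if self.cells.shape[1] != nodes_per_cell(self.cell_type):
            raise ValueError("cell connectivity does not match cell type")

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ref_coords)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self, config: str = "ref") -> np.ndarray:
        """Signed cell volumes in the reference or current configuration."""
        coords = self.ref_coords if config == "ref" else self.cur_coords
        xe = coords[self.cells]  # (ne, nn, 3)
        if self.cell_type == TET4:
            d = xe[:, 1:, :] - xe[:, :1, :]
            return np.linalg.det(d) / 6.0
        rule = elements.quadrature_rule(self.cell_type, 3)
        _, dN = elements.shape_table(self.cell_type, rule)
        jac = np.einsum("eki,qkj->eqij", xe, dN)
        return np.einsum("q,eq->e", rule.weights, np.linalg.det(jac))

    def check_volumes(self, config: str = "ref") -> None:
        vols = self.cell_volumes(config)
        if vols.min() <= 0.0:
            bad = int(np.argmin(vols))
            raise MeshQualityError(
                f"cell {bad} has non-positive volume {vols.min():g} "
                f"in the {config!r} configuration"
            )

    def boundary_facets_by_tag(self, tag: str):
        return [bf for bf in self.boundary_facets if bf[3] == tag]

    def boundary_tags(self):
        return sorted({bf[3] for bf in self.boundary_facets})

    def copy(self) -> "Mesh":
        return Mesh(
            ref_coords=self.ref_coords.copy(),
            cells=self.cells.copy(),
            cell_type=self.cell_type,
            cur_coords=self.cur_coords.copy(),
            boundary_facets=list(self.boundary_facets),
            interior_faces=list(self.interior_faces),
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
        )


# -- facet census --------------------------------------------------------

def _facet_census(cells: np.ndarray, cell_type: str) -> dict:
    """Map sorted facet node tuple -> list of (cell, local facet id)."""
    census: dict[tuple, list] = {}
    lf = local_facets(cell_type)
    for c, conn in enumerate(cells):
        for fid, loc in enumerate(lf):
            key = tuple(sorted(int(conn[i]) for i in loc))
            census.setdefault(key, []).append((c, fid))
    return census


def extract_interior_faces(mesh: Mesh) -> list:
    """Faces shared by exactly two cells, as ``(left, right, nodes)``.

    Boundary facets (owned by a single cell) are excluded: the stabilization
    sum runs over element boundaries minus the domain boundary.  The face
    node ring is the left cell's outward-oriented facet.
    """
    census = _facet_census(mesh.cells, mesh.cell_type)
    lf = local_facets(mesh.cell_type)
    faces = []
    for key, owners in census.items():
        if len(owners) > 2:
            raise TopologyError(
                f"facet {key} shared by {len(owners)} cells; mesh is non-conforming"
            )
        if len(owners) == 2:
            owners = sorted(owners)
            (cl, fl), (cr, _) = owners
            ring = tuple(int(mesh.cells[cl][i]) for i in lf[fl])
            faces.append((cl, cr, ring))
    faces.sort(key=lambda f: (f[0], f[1]))
    return faces


def _finish_mesh(mesh: Mesh, tag_fn) -> Mesh:
    """Fill interior faces and tag the boundary from the facet census."""
    census = _facet_census(mesh.cells, mesh.cell_type)
    lf = local_facets(mesh.cell_type)
    mesh.interior_faces = extract_interior_faces(mesh)
    boundary = []
    for key, owners in census.items():
        if len(owners) == 1:
            (c, fid) = owners[0]
            ring = tuple(int(mesh.cells[c][i]) for i in lf[fid])
            boundary.append((c, fid, ring, tag_fn(mesh.ref_coords[list(ring)])))
    boundary.sort(key=lambda b: (b[0], b[1]))
    mesh.boundary_facets = boundary
    mesh.check_volumes("ref")
    return mesh


def _box_tagger(L, tol):
    Lx, Ly, Lz = L

    def tag(face_coords):
        c = face_coords
        for val, name in (
            (0.0, "x0"), (Lx, "x1"),
        ):
            if np.all(np.abs(c[:, 0] - val) < tol):
                return name
        for val, name in ((0.0, "y0"), (Ly, "y1")):
            if np.all(np.abs(c[:, 1] - val) < tol):
                return name
        for val, name in ((0.0, "z0"), (Lz, "z1")):
            if np.all(np.abs(c[:, 2] - val) < tol):
                return name
        return "boundary"

    return tag


def build_box_hex_mesh(nx: int, ny: int, nz: int, Lx: float = 1.0, Ly: float = 1.0,
                       Lz: float = 1.0) -> Mesh:
    """Structured hexahedral box ``[0,Lx] x [0,Ly] x [0,Lz]``.

    Boundary facets are tagged ``{x0, x1, y0, y1, z0, z1}`` by the face of
    the box they lie on.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError(f"cell counts must be >= 1, got {(nx, ny, nz)}")
    if min(Lx, Ly, Lz) <= 0.0:
        raise ValueError(f"box lengths must be positive, got {(Lx, Ly, Lz)}")
    xs = np.linspace(0.0, Lx, nx + 1)
    ys = np.linspace(0.0, Ly, ny + 1)
    zs = np.linspace(0.0, Lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")], axis=1)

    def nid(i, j, k):
        return i + j * (nx + 1) + k * (nx + 1) * (ny + 1)

    cells = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                cells.append(
                    [
                        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    mesh = Mesh(ref_coords=coords, cells=np.array(cells), cell_type=HEX8)
    tol = 1e-9 * max(Lx, Ly, Lz)
    return _finish_mesh(mesh, _box_tagger((Lx, Ly, Lz), tol))


# -- cylinder ------------------------------------------------------------

def _disk_rings(nr: int):
    """Hex-pattern disk point layout: ring i has max(1, 6i) nodes."""
    ring_start = [0]
    angles = [np.array([0.0])]
    for i in range(1, nr + 1):
        n = 6 * i
        ring_start.append(ring_start[-1] + len(angles[-1]))
        angles.append(2.0 * np.pi * np.arange(n) / n)
    return ring_start, angles


def _triangulate_disk(nr: int):
    """Triangles of the hex-pattern disk, plus the 2D node coordinates."""
    ring_start, angles = _disk_rings(nr)
    pts = []
    for i, ang in enumerate(angles):
        r = i / nr
        pts.extend((r * np.cos(a), r * np.sin(a)) for a in ang)
    tris = []
    # centre fan
    s1 = ring_start[1]
    for j in range(6):
        tris.append((0, s1 + j, s1 + (j + 1) % 6))
    # bands: merge the two rings by angle
    for i in range(2, nr + 1):
        si, so = ring_start[i - 1], ring_start[i]
        ni, no = 6 * (i - 1), 6 * i
        ai, ao = angles[i - 1], angles[i]
        ii = jo = 0
        while ii < ni or jo < no:
            inner = si + ii % ni
            outer = so + jo % no
            adv_inner = ai[(ii + 1) % ni] + (2 * np.pi if ii + 1 >= ni else 0.0)
            adv_outer = ao[(jo + 1) % no] + (2 * np.pi if jo + 1 >= no else 0.0)
            if jo < no and (ii >= ni or adv_outer <= adv_inner):
                tris.append((inner, outer, so + (jo + 1) % no))
                jo += 1
            else:
                tris.append((inner, outer, si + (ii + 1) % ni))
                ii += 1
    return np.array(pts), tris


def _split_prism(v):
    """Conforming 3-tet split of prism (bottom v0 v1 v2, top v3 v4 v5).

    Quad faces are cut by the diagonal through each face's smallest global
    node index, which matches across neighbouring prisms.
    """
    v = list(v)
    # rotate so the smallest-index vertex sits at position 0 (keep bottom/top)
    if min(v[:3]) > min(v[3:]):
        v = [v[3], v[5], v[4], v[0], v[2], v[1]]  # flip upside down
    rot = int(np.argmin(v[:3]))
    b = [v[(rot + s) % 3] for s in range(3)]
    t = [v[3 + (rot + s) % 3] for s in range(3)]
    v0, v1, v2, v3, v4, v5 = b + t
    if min(v1, v5) < min(v2, v4):
        return [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
    return [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]


def _orient_tets(cells, coords):
    cells = np.asarray(cells, dtype=np.int64)
    d = coords[cells[:, 1:]] - coords[cells[:, :1]]
    neg = np.linalg.det(d) < 0.0
    cells[neg] = cells[neg][:, [0, 2, 1, 3]]
    return cells


def build_cylinder_tet_mesh(radius: float, height: float, target_cells: int,
                            aspect_limit: float = 2.0) -> Mesh:
    """Structured tetrahedral cylinder (triangulated disk extruded in layers).

    The disk uses the hexagonal ring pattern (ring i carries 6i nodes), each
    prism of the extrusion splits into three conforming tets, so the cell
    count is ``18 nr^2 nz``.  ``nr`` and ``nz`` are chosen to approach
    ``target_cells`` while keeping the layer height within ``aspect_limit``
    of the radial spacing.  Boundary tags: ``bottom``, ``top``, ``lateral``;
    node set ``axis`` collects the nodes on the cylinder axis.
    """
    if radius <= 0.0 or height <= 0.0:
        raise ValueError("radius and height must be positive")
    if target_cells < 18:
        raise ValueError("target_cells must be at least 18 (one ring, one layer)")
    best = None
    for nr in range(1, 40):
        dz_ref = radius / nr
        for nz in range(1, 400):
            if not (1.0 / aspect_limit) <= (height / nz) / dz_ref <= aspect_limit:
                continue
            cells = 18 * nr * nr * nz
            score = abs(cells - target_cells)
            if best is None or score < best[0]:
                best = (score, nr, nz)
    _, nr, nz = best
    pts2d, tris = _triangulate_disk(nr)
    n2d = len(pts2d)
    coords = np.empty((n2d * (nz + 1), 3))
    for layer in range(nz + 1):
        coords[layer * n2d:(layer + 1) * n2d, :2] = pts2d * radius
        coords[layer * n2d:(layer + 1) * n2d, 2] = height * layer / nz
    cells = []
    for layer in range(nz):
        lo, hi = layer * n2d, (layer + 1) * n2d
        for (a, b, c) in tris:
            cells.extend(_split_prism((lo + a, lo + b, lo + c, hi + a, hi + b, hi + c)))
    cells = _orient_tets(cells, coords)

    tol = 1e-9 * max(radius, height)

    def tag(face_coords):
        if np.all(np.abs(face_coords[:, 2]) < tol):
            return "bottom"
        if np.all(np.abs(face_coords[:, 2] - height) < tol):
            return "top"
        return "lateral"

    mesh = Mesh(ref_coords=coords, cells=cells, cell_type=TET4)
    mesh = _finish_mesh(mesh, tag)
    r2 = coords[:, 0] ** 2 + coords[:, 1] ** 2
    mesh.node_sets["axis"] = np.nonzero(r2 < tol * tol)[0]
    mesh.node_sets["outer"] = np.nonzero(
        np.abs(np.sqrt(r2) - radius) < 1e-9 * radius
    )[0]
    # nodes on the y = 0 symmetry plane: pinning their tangential (y)
    # displacement removes the rigid rotation about the axis without
    # disturbing an axisymmetric solution
    mesh.node_sets["y0_plane"] = np.nonzero(np.abs(coords[:, 1]) < tol)[0]
    return mesh


# -- hex -> tet splitting ------------------------------------------------

def tetrahedralize(mesh: Mesh, scheme: str = "six_per_hex") -> Mesh:
    """Split a hexahedral mesh into a conforming tetrahedral mesh.

    ``six_per_hex`` cones each hex from its smallest-index corner over the
    min-index-diagonal triangulation of the three far faces; the face
    diagonal rule is face-intrinsic, so the split conforms across cells.
    ``twenty_four_per_hex`` adds face and body centres: each quad face
    yields four triangles which cone to the body centre (24 tets per hex).
    Boundary tags are inherited from the parent quad facets.
    """
    if mesh.cell_type != HEX8:
        raise ValueError("tetrahedralize expects a hex8 mesh")
    if scheme not in ("six_per_hex", "twenty_four_per_hex"):
        raise ValueError(f"unknown scheme {scheme!r}")
    coords = mesh.ref_coords
    quad_tag = {tuple(sorted(bf[2])): bf[3] for bf in mesh.boundary_facets}
    tets = []
    if scheme == "six_per_hex":
        new_coords = coords.copy()
        for conn in mesh.cells:
            conn = [int(n) for n in conn]
            v0 = conn[int(np.argmin(conn))]
            pos = conn.index(v0)
            for loc in local_facets(HEX8):
                quad = [conn[i] for i in loc]
                if v0 in quad:
                    continue
                # split far face by the diagonal through its min corner
                m = int(np.argmin(quad))
                q = quad[m:] + quad[:m]
                for tri in ((q[0], q[1], q[2]), (q[0], q[2], q[3])):
                    tets.append((v0,) + tri)
            del pos
    else:
        new_pts = []
        face_id = {}
        for conn in mesh.cells:
            for loc in local_facets(HEX8):
                key = tuple(sorted(int(conn[i]) for i in loc))
                if key not in face_id:
                    face_id[key] = len(coords) + len(new_pts)
                    new_pts.append(coords[list(key)].mean(axis=0))
        centers = coords[mesh.cells].mean(axis=1)
        center_id = len(coords) + len(new_pts)
        new_coords = np.vstack([coords, np.array(new_pts).reshape(-1, 3), centers])
        for c, conn in enumerate(mesh.cells):
            cid = center_id + c
            for loc in local_facets(HEX8):
                quad = [int(conn[i]) for i in loc]
                fid = face_id[tuple(sorted(quad))]
                for a, b in zip(quad, quad[1:] + quad[:1]):
                    tets.append((cid, a, b, fid))
    tets = _orient_tets(tets, new_coords)

    def tag(face_coords):  # placeholder, replaced below
        return "boundary"

    out = Mesh(ref_coords=new_coords, cells=tets, cell_type=TET4,
               node_sets={k: np.array(v) for k, v in mesh.node_sets.items()})
    out = _finish_mesh(out, tag)

    # inherit tags: corner nodes of each boundary triangle lie in exactly
    # one parent quad (face centres are resolved through their defining quad)
    node_to_quads: dict[int, set] = {}
    for qi, key in enumerate(quad_tag):
        for n in key:
            node_to_quads.setdefault(n, set()).add(key)
    if scheme == "twenty_four_per_hex":
        fc_owner = {}
        for key in quad_tag:
            fid = face_id.get(key)
            if fid is not None:
                fc_owner[fid] = key
    fixed = []
    for (c, fid_loc, ring, _t) in out.boundary_facets:
        cands = None
        for n in ring:
            owners = (
                {fc_owner[n]} if scheme == "twenty_four_per_hex" and n in fc_owner
                else node_to_quads.get(n)
            )
            if owners is None:
                continue
            cands = set(owners) if cands is None else cands & owners
        tagname = quad_tag[next(iter(cands))] if cands else "boundary"
        fixed.append((c, fid_loc, ring, tagname))
    out.boundary_facets = fixed
    return out
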