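"""Reference elements, quadrature and isoparametric geometry.

Supports the two low-order cells the method uses: 4-node tetrahedra
(reference simplex with vertices at the origin and the unit points) and
8-node hexahedra (reference cube ``[-1, 1]^3``, VTK corner ordering).
Displacement and flux live in the (tri)linear nodal space on these cells;
pressure is constant per cell, so no reference element is needed for it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import roots_jacobi

TET4 = "tet4"
HEX8 = "hex8"

#: corner sign pattern of the VTK hex8 ordering on [-1,1]^3
_HEX_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)

#: local facets with outward orientation (right-hand rule) in the reference cell
TET_FACETS = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))
HEX_FACETS = (
    (0, 3, 2, 1),  # z = -1
    (4, 5, 6, 7),  # z = +1
    (0, 1, 5, 4),  # y = -1
    (1, 2, 6, 5),  # x = +1
    (2, 3, 7, 6),  # y = +1
    (0, 4, 7, 3),  # x = -1
)


class DomainError(ValueError):
    """Evaluation point outside the reference cell."""


class DegenerateGeometryError(ValueError):
    """Collinear face vertices or singular/inverted cell map."""


def nodes_per_cell(cell_type: str) -> int:
    if cell_type == TET4:
        return 4
    if cell_type == HEX8:
        return 8
    raise ValueError(f"unknown cell type {cell_type!r}")


def local_facets(cell_type: str):
    return TET_FACETS if cell_type == TET4 else HEX_FACETS


def shape_functions(cell_type: str, point, tol: float = 1e-10):
    """Nodal basis values and local gradients at one reference point.

    Returns ``(values, grads)`` with shapes ``(n,)`` and ``(n, 3)``.  The
    basis is a partition of unity, so values sum to one and gradients sum
    to the zero vector.
    """
    xi = np.asarray(point, dtype=float)
    if cell_type == TET4:
        x, y, z = xi
        if min(x, y, z) < -tol or x + y + z > 1.0 + tol:
            raise DomainError(f"point {xi} outside reference tetrahedron")
        vals = np.array([1.0 - x - y - z, x, y, z])
        grads = np.array(
            [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        return vals, grads
    if cell_type == HEX8:
        if np.any(np.abs(xi) > 1.0 + tol):
            raise DomainError(f"point {xi} outside reference cube")
        s = _HEX_SIGNS
        fac = 1.0 + s * xi  # (8, 3)
        vals = 0.125 * fac.prod(axis=1)
        grads = np.empty((8, 3))
        for d in range(3):
            others = [e for e in range(3) if e != d]
            grads[:, d] = 0.125 * s[:, d] * fac[:, others].prod(axis=1)
        return vals, grads
    raise ValueError(f"unknown cell type {cell_type!r}")


@dataclass(frozen=True)
class QuadratureRule:
    """Positive-weight rule on the reference cell, exact to ``degree``."""

    cell_type: str
    degree: int
    points: np.ndarray  # (nq, 3)
    weights: np.ndarray  # (nq,)

    @property
    def npoints(self) -> int:
        return len(self.weights)


# fully symmetric 4-point degree-2 rule on the unit tetrahedron
_TET_A = 0.5854101966249685
_TET_B = 0.1381966011250105


def quadrature_rule(cell_type: str, degree: int) -> QuadratureRule:
    """Volume quadrature on the reference cell.

    Hexahedra use tensor Gauss–Legendre; tetrahedra use the classical
    1- and 4-point symmetric rules for degrees 1–2 and a conical-product
    (Duffy) rule for degrees 3–4.  All rules have positive weights.
    """
    if degree < 1 or degree > 4:
        raise ValueError(f"quadrature degree {degree} unsupported (need 1-4)")
    if cell_type == HEX8:
        n = (degree + 2) // 2  # 2n-1 >= degree
        x, w = leggauss(n)
        pts = np.array(list(itertools.product(x, x, x)))
        wts = np.array([wx * wy * wz for wx, wy, wz in itertools.product(w, w, w)])
        return QuadratureRule(HEX8, degree, pts, wts)
    if cell_type == TET4:
        if degree == 1:
            pts = np.array([[0.25, 0.25, 0.25]])
            wts = np.array([1.0 / 6.0])
        elif degree == 2:
            a, b = _TET_A, _TET_B
            pts = np.array(
                [[b, b, b], [a, b, b], [b, a, b], [b, b, a]]
            )
            wts = np.full(4, 1.0 / 24.0)
        else:
            n = (degree + 2) // 2
            xg, wx = roots_jacobi(n, 2.0, 0.0)
            yg, wy = roots_jacobi(n, 1.0, 0.0)
            zg, wz = leggauss(n)
            xg = (xg + 1.0) / 2.0
            yg = (yg + 1.0) / 2.0
            zg = (zg + 1.0) / 2.0
            # account for interval mapping of the weight functions
            wx = wx / 8.0  # (1-x)^2 dx on [0,1]
            wy = wy / 4.0  # (1-y)   dy on [0,1]
            wz = wz / 2.0
            pts, wts = [], []
            for (x, ax), (y, ay), (z, az) in itertools.product(
                zip(xg, wx), zip(yg, wy), zip(zg, wz)
            ):
                # Duffy map from the unit cube to the unit tetrahedron
                pts.append((x, y * (1 - x), z * (1 - x) * (1 - y)))
                wts.append(ax * ay * az)
            pts = np.array(pts)
            wts = np.array(wts)
        return QuadratureRule(TET4, degree, pts, wts)
    raise ValueError(f"unknown cell type {cell_type!r}")


def shape_table(cell_type: str, rule: QuadratureRule):
    """Basis values/gradients tabulated at the rule points.

    Returns ``(N, dN)`` with shapes ``(nq, n)`` and ``(nq, n, 3)``.
    """
    vals, grads = [], []
    for pt in rule.points:
        v, g = shape_functions(cell_type, pt)
        vals.append(v)
        grads.append(g)
    return np.array(vals), np.array(grads)


def physical_gradients(cell_coords, cell_type: str, point):
    """Gradients of the nodal basis w.r.t. the given nodal coordinates.

    Returns ``(grads, detJ)``; ``grads[k]`` is the spatial gradient of basis
    function ``k``.  Raises :class:`DegenerateGeometryError` on a singular or
    inverted map.
    """
    coords = np.asarray(cell_coords, dtype=float)
    _, dN = shape_functions(cell_type, point)
    jac = coords.T @ dN  # J_ij = d x_i / d xi_j
    det = np.linalg.det(jac)
    if det <= 0.0 or not np.isfinite(det):
        raise DegenerateGeometryError(
            f"singular or inverted element map (det J = {det:g})"
        )
    grads = dN @ np.linalg.inv(jac)
    return grads, det


def cell_volume(cell_coords, cell_type: str, degree: int = 2) -> float:
    """Signed volume of one cell from quadrature of the map Jacobian."""
    coords = np.asarray(cell_coords, dtype=float)
    rule = quadrature_rule(cell_type, degree)
    _, dN = shape_table(cell_type, rule)
    jac = np.einsum("ki,qkj->qij", coords, dN)
    return float(np.einsum("q,q->", rule.weights, np.linalg.det(jac)))


@dataclass(frozen=True)
class FaceGeometry:
    """Metric data of a (possibly warped) triangular or quadrilateral face."""

    area: float
    unit_normal: np.ndarray
    diameter: float


def face_geometry(face_coords) -> FaceGeometry:
    """Area, unit normal and diameter of a face given its vertex ring.

    Vertices are ordered so the right-hand rule gives the outward normal.
    Quadrilaterals may be warped: the normal is that of the cross product of
    the diagonals (best-fit plane) and the area is integrated with a 2x2
    Gauss rule on the bilinear patch.
    """
    x = np.asarray(face_coords, dtype=float)
    nv = len(x)
    diam = max(
        np.linalg.norm(x[i] - x[j]) for i in range(nv) for j in range(i + 1, nv)
    )
    if nv == 3:
        cr = np.cross(x[1] - x[0], x[2] - x[0])
        nrm = np.linalg.norm(cr)
        if nrm <= 1e-14 * max(diam, 1.0) ** 2:
            raise DegenerateGeometryError("collinear face vertices")
        return FaceGeometry(0.5 * nrm, cr / nrm, diam)
    if nv == 4:
        cr = np.cross(x[2] - x[0], x[3] - x[1])
        nrm = np.linalg.norm(cr)
        if nrm <= 1e-14 * max(diam, 1.0) ** 2:
            raise DegenerateGeometryError("collinear face vertices")
        g = 1.0 / np.sqrt(3.0)
        area = 0.0
        for xi, eta in itertools.product((-g, g), repeat=2):
            du = 0.25 * (
                -(1 - eta) * x[0] + (1 - eta) * x[1] + (1 + eta) * x[2] - (1 + eta) * x[3]
            )
            dv = 0.25 * (
                -(1 - xi) * x[0] - (1 + xi) * x[1] + (1 + xi) * x[2] + (1 - xi) * x[3]
            )
            area += np.linalg.norm(np.cross(du, dv))
        return FaceGeometry(area, cr / nrm, diam)
    raise ValueError("faces must have 3 or 4 vertices")


def face_quadrature(face_coords):
    """Surface quadrature points, weights and outward normals for one face.

    Triangles use the centroid rule (exact for linear integrands);
    quadrilaterals a 2x2 Gauss rule on the bilinear patch.  Weights carry
    the surface measure, normals follow the vertex-ring orientation.

    Returns ``(points (nq,3), weights (nq,), normals (nq,3))``.
    """
    x = np.asarray(face_coords, dtype=float)
    if len(x) == 3:
        cr = np.cross(x[1] - x[0], x[2] - x[0])
        nrm = np.linalg.norm(cr)
        if nrm <= 0.0:
            raise DegenerateGeometryError("degenerate triangular face")
        return (
            x.mean(axis=0)[None, :],
            np.array([0.5 * nrm]),
            (cr / nrm)[None, :],
        )
    if len(x) == 4:
        g = 1.0 / np.sqrt(3.0)
        pts, wts, nrms = [], [], []
        for xi, eta in itertools.product((-g, g), repeat=2):
            sh = 0.25 * np.array(
                [
                    (1 - xi) * (1 - eta),
                    (1 + xi) * (1 - eta),
                    (1 + xi) * (1 + eta),
                    (1 - xi) * (1 + eta),
                ]
            )
            du = 0.25 * (
                -(1 - eta) * x[0] + (1 - eta) * x[1] + (1 + eta) * x[2] - (1 + eta) * x[3]
            )
            dv = 0.25 * (
                -(1 - xi) * x[0] - (1 + xi) * x[1] + (1 + xi) * x[2] + (1 - xi) * x[3]
            )
            cr = np.cross(du, dv)
            nrm = np.linalg.norm(cr)
            if nrm <= 0.0:
                raise DegenerateGeometryError("degenerate quadrilateral face")
            pts.append(sh @ x)
            wts.append(nrm)
            nrms.append(cr / nrm)
        return np.array(pts), np.array(wts), np.array(nrms)
    raise ValueError("faces must have 3 or 4 vertices")
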