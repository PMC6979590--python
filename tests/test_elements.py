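"""Reference elements: shape functions, quadrature exactness, geometry."""

import itertools
import math

import numpy as np
import pytest

from porofem.elements import (
    DegenerateGeometryError,
    DomainError,
    face_geometry,
    face_quadrature,
    physical_gradients,
    quadrature_rule,
    shape_functions,
    shape_table,
)


def exact_monomial_integral(cell_type, a, b, c):
    """Closed-form integral of x^a y^b z^c over the reference cell."""
    if cell_type == "tet4":
        return (
            math.factorial(a) * math.factorial(b) * math.factorial(c)
            / math.factorial(a + b + c + 3)
        )
    def seg(k):  # integral of t^k over [-1, 1]
        return 0.0 if k % 2 else 2.0 / (k + 1)
    return seg(a) * seg(b) * seg(c)


class TestShapeFunctions:
    def test_tet_barycentre_values(self):
        vals, _ = shape_functions("tet4", (0.25, 0.25, 0.25))
        assert np.allclose(vals, 0.25)

    def test_hex_vertex_kronecker(self):
        corners = [
            (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
            (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
        ]
        for k, corner in enumerate(corners):
            vals, _ = shape_functions("hex8", corner)
            assert np.allclose(vals, np.eye(8)[k], atol=1e-14)

    @pytest.mark.parametrize("cell_type,pt", [
        ("tet4", (0.3, 0.2, 0.1)),
        ("hex8", (0.4, -0.7, 0.2)),
    ])
    def test_partition_of_unity(self, cell_type, pt):
        vals, grads = shape_functions(cell_type, pt)
        assert vals.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(grads.sum(axis=0), 0.0, atol=1e-14)

    @pytest.mark.parametrize("cell_type,pt", [
        ("tet4", (0.5, 0.5, 0.5)),
        ("hex8", (1.5, 0.0, 0.0)),
    ])
    def test_outside_reference_cell_raises(self, cell_type, pt):
        with pytest.raises(DomainError):
            shape_functions(cell_type, pt)


class TestQuadrature:
    def test_hex_degree3_is_2x2x2_gauss(self):
        rule = quadrature_rule("hex8", 3)
        assert rule.npoints == 8
        assert rule.weights.sum() == pytest.approx(8.0)

    def test_tet_degree2_is_4_point(self):
        rule = quadrature_rule("tet4", 2)
        assert rule.npoints == 4
        assert rule.weights.sum() == pytest.approx(1.0 / 6.0)

    @pytest.mark.parametrize("cell_type", ["tet4", "hex8"])
    @pytest.mark.parametrize("degree", [1, 2, 3, 4])
    def test_monomial_exactness(self, cell_type, degree):
        rule = quadrature_rule(cell_type, degree)
        assert np.all(rule.weights > 0.0)
        for a, b, c in itertools.product(range(degree + 1), repeat=3):
            if a + b + c > degree:
                continue
            vals = rule.points[:, 0] ** a * rule.points[:, 1] ** b * rule.points[:, 2] ** c
            got = float(rule.weights @ vals)
            assert got == pytest.approx(
                exact_monomial_integral(cell_type, a, b, c), abs=1e-12
            ), (a, b, c)

    def test_unsupported_degree_raises(self):
        with pytest.raises(ValueError):
            quadrature_rule("tet4", 9)


class TestPhysicalGradients:
    def test_linear_field_gradient_on_reference_tet(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        grads, det = physical_gradients(coords, "tet4", (0.25, 0.25, 0.25))
        nodal = 2 * coords[:, 0] + 3 * coords[:, 1] + 5 * coords[:, 2]
        assert np.allclose(nodal @ grads, [2, 3, 5], atol=1e-13)
        assert det == pytest.approx(1.0)

    def test_dilation_scales_jacobian(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        _, det1 = physical_gradients(coords, "tet4", (0.25, 0.25, 0.25))
        _, det2 = physical_gradients(2 * coords, "tet4", (0.25, 0.25, 0.25))
        assert det2 / det1 == pytest.approx(8.0)

    def test_random_affine_cell_reproduces_identity(self, rng):
        # gradient of the coordinate fields must be the identity (direct
        # matrix-inverse oracle: the map is affine, so this is exact)
        A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        while np.linalg.det(A) <= 0.1:
            A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        coords = ref @ A.T + rng.standard_normal(3)
        grads, _ = physical_gradients(coords, "tet4", (0.2, 0.3, 0.1))
        assert np.allclose(coords.T @ grads, np.eye(3), atol=1e-12)

    def test_inverted_cell_raises(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, -1]])
        with pytest.raises(DegenerateGeometryError):
            physical_gradients(coords, "tet4", (0.25, 0.25, 0.25))


class TestFaceGeometry:
    def test_unit_square(self):
        fg = face_geometry([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert fg.area == pytest.approx(1.0)
        assert fg.diameter == pytest.approx(np.sqrt(2.0))
        assert np.allclose(fg.unit_normal, [0, 0, 1])

    def test_right_unit_triangle(self):
        fg = face_geometry([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert fg.area == pytest.approx(0.5)
        assert fg.diameter == pytest.approx(np.sqrt(2.0))

    def test_warped_quad_area_matches_surface_quadrature(self, rng):
        quad = np.array([[0, 0, 0], [1, 0, 0.2], [1.1, 1, 0], [0, 1, -0.1]], float)
        fg = face_geometry(quad)
        # refined surface-quadrature oracle on the bilinear patch
        n = 40
        area = 0.0
        for i in range(n):
            for j in range(n):
                xi = -1 + (2 * i + 1) / n
                eta = -1 + (2 * j + 1) / n
                du = 0.25 * (-(1 - eta) * quad[0] + (1 - eta) * quad[1]
                             + (1 + eta) * quad[2] - (1 + eta) * quad[3])
                dv = 0.25 * (-(1 - xi) * quad[0] - (1 + xi) * quad[1]
                             + (1 + xi) * quad[2] + (1 - xi) * quad[3])
                area += np.linalg.norm(np.cross(du, dv)) * (2 / n) ** 2
        assert fg.area == pytest.approx(area, abs=1e-4)

    def test_collinear_vertices_raise(self):
        with pytest.raises(DegenerateGeometryError):
            face_geometry([[0, 0, 0], [1, 0, 0], [2, 0, 0]])

    def test_face_quadrature_integrates_linear_fields(self):
        tri = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]])
        pts, wts, nrms = face_quadrature(tri)
        # int (x + y) over the triangle with vertices (0,0),(2,0),(0,2) = 8/3
        got = float(sum(w * (p[0] + p[1]) for p, w in zip(pts, wts)))
        assert got == pytest.approx(8.0 / 3.0)
        assert np.allclose(nrms, [0, 0, 1])


def test_shape_table_matches_pointwise_evaluation():
    rule = quadrature_rule("hex8", 3)
    N, dN = shape_table("hex8", rule)
    v, g = shape_functions("hex8", rule.points[3])
    assert np.allclose(N[3], v)
    assert np.allclose(dN[3], g)
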