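"""Unit tests of the FEM core: quadrature, spaces, assembly kernels."""

from itertools import product
from math import factorial

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from icpulse.fem import assemble as asm
from icpulse.fem.quadrature import simplex_rule
from icpulse.fem.spaces import FunctionSpace
from icpulse.geometry import FacetTag, build_two_box_2d, build_unit_cube


def _monomial_exact(dim, a):
    num = 1
    for ai in a:
        num *= factorial(ai)
    return num / factorial(dim + sum(a))


@pytest.mark.parametrize("dim", [1, 2, 3])
@pytest.mark.parametrize("deg", [1, 2, 3, 4, 5])
def test_quadrature_exactness(dim, deg):
    pts, w = simplex_rule(dim, deg)
    for a in product(range(deg + 1), repeat=dim):
        if sum(a) > deg:
            continue
        val = (np.prod(pts ** np.asarray(a), axis=1) * w).sum()
        assert val == pytest.approx(_monomial_exact(dim, a), rel=1e-12,
                                    abs=1e-15)


class TestSpaces:
    def test_p2_interpolates_quadratics_exactly(self):
        dom = build_two_box_2d(3)
        S = FunctionSpace(dom.mesh, 2)
        f = lambda p: 1 + p[:, 0] ** 2 - 2 * p[:, 0] * p[:, 1] + p[:, 1]
        assert S.l2_error(S.interpolate(f), f) < 1e-13

    def test_p1_interpolates_linears_exactly(self):
        dom = build_unit_cube(2)
        S = FunctionSpace(dom.mesh, 1)
        f = lambda p: 2 * p[:, 0] - p[:, 1] + 3 * p[:, 2] + 1
        assert S.l2_error(S.interpolate(f), f) < 1e-13

    def test_point_evaluation(self):
        dom = build_two_box_2d(3)
        S = FunctionSpace(dom.mesh, 2)
        f = lambda p: p[:, 0] ** 2 + p[:, 1]
        vec = S.interpolate(f)
        pts = np.array([[0.31, 0.42], [0.77, -0.5]])
        assert np.allclose(S.eval_at_points(vec, pts), f(pts), atol=1e-13)

    def test_outside_point_raises(self):
        dom = build_two_box_2d(2)
        S = FunctionSpace(dom.mesh, 1)
        with pytest.raises(ValueError):
            S.eval_at_points(np.zeros(S.ndof), np.array([[5.0, 5.0]]))


class TestAssembly:
    def test_mass_integrates_volume(self):
        dom = build_unit_cube(2)
        S = FunctionSpace(dom.mesh, 2)
        r, c, v = asm.mass(S, S)
        M = sp.coo_matrix((v, (r, c)), shape=(S.ndof, S.ndof))
        one = np.ones(S.ndof)
        assert one @ (M @ one) == pytest.approx(1.0, rel=1e-12)

    def test_stiffness_annihilates_constants(self):
        dom = build_unit_cube(2)
        S = FunctionSpace(dom.mesh, 2)
        r, c, v = asm.stiffness(S, S)
        K = sp.coo_matrix((v, (r, c)), shape=(S.ndof, S.ndof)).tocsr()
        assert np.abs(K @ np.ones(S.ndof)).max() < 1e-12

    def test_elastic_annihilates_rigid_motion(self):
        dom = build_unit_cube(2)
        V = FunctionSpace(dom.mesh, 2, ncomp=3)
        r, c, v = asm.elastic(V, V, mu=1.0)
        K = sp.coo_matrix((v, (r, c)), shape=(V.ndof, V.ndof)).tocsr()
        # translation + infinitesimal rotation
        rig = V.interpolate(lambda p: np.stack(
            [1.0 - p[:, 1], 2.0 + p[:, 0], np.full(len(p), 0.5)], axis=1))
        assert np.abs(K @ rig).max() < 1e-11

    def test_div_coupling_exact(self):
        dom = build_unit_cube(2)
        V = FunctionSpace(dom.mesh, 2, ncomp=3)
        Q = FunctionSpace(dom.mesh, 1)
        r, c, v = asm.div_coupling(Q, V)
        B = sp.coo_matrix((v, (r, c)), shape=(Q.ndof, V.ndof)).tocsr()
        # div(x, y, z) = 3; pairing with q=1 gives 3*volume
        vec = V.interpolate(lambda p: p)
        assert np.ones(Q.ndof) @ (B @ vec) == pytest.approx(3.0, rel=1e-12)

    def test_poisson_p2_convergence(self):
        ue = lambda p: np.sin(np.pi * p[:, 0]) * np.sin(np.pi * p[:, 1])
        ff = lambda p: 2 * np.pi ** 2 * ue(p)
        errs = []
        for n in (4, 8):
            dom = build_two_box_2d(n)
            S = FunctionSpace(dom.mesh, 2, cells=dom.csf_cells)
            r, c, v = asm.stiffness(S, S)
            K = sp.coo_matrix((v, (r, c)), shape=(S.ndof, S.ndof)).tocsr()
            b = asm.volume_load(S, ff)
            bd = S.boundary_scalar_dofs([FacetTag.SKULL, FacetTag.INTERFACE])
            A = asm.apply_dirichlet(K, b, bd, np.zeros(len(bd)))
            errs.append(S.l2_error(spsolve(A, b), ue))
        assert errs[1] < errs[0] / 6.5  # cubic convergence

    def test_facet_flux_divergence_free(self):
        cube = build_unit_cube(2)
        V = FunctionSpace(cube.mesh, 2, ncomp=3)
        ctx = asm.FacetContext(cube.mesh, cube.mesh.boundary_facets,
                               cube.mesh.facet_cells[
                                   cube.mesh.boundary_facets, 0])
        vec = V.interpolate(lambda p: np.stack(
            [p[:, 0] ** 2, -2 * p[:, 0] * p[:, 1], p[:, 1]], axis=1))
        assert asm.facet_flux(ctx, V, vec) == pytest.approx(0.0, abs=1e-13)

    def test_facet_flux_unit_divergence(self):
        cube = build_unit_cube(2)
        V = FunctionSpace(cube.mesh, 2, ncomp=3)
        ctx = asm.FacetContext(cube.mesh, cube.mesh.boundary_facets,
                               cube.mesh.facet_cells[
                                   cube.mesh.boundary_facets, 0])
        vec = V.interpolate(
            lambda p: np.stack([p[:, 0], 0 * p[:, 1], 0 * p[:, 2]], axis=1))
        assert asm.facet_flux(ctx, V, vec) == pytest.approx(1.0, rel=1e-12)
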