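"""Vectorized assembly kernels for volume and facet (interface) forms.

All kernels return COO triplets ``(rows, cols, vals)`` indexed in the dof
numbering of the supplied test/trial spaces; the caller offsets them into a
global block system.  Cells are affine, so Jacobians are constant per cell.
"""

from __future__ import annotations

from math import factorial

import numpy as np
import scipy.sparse as sp

from icpulse.fem.quadrature import simplex_rule
from icpulse.fem.spaces import FunctionSpace

__all__ = [
    "mass",
    "stiffness",
    "elastic",
    "vector_mass",
    "div_coupling",
    "volume_load",
    "facet_vec_normal_scalar",
    "facet_tangential",
    "facet_normal_load",
    "facet_flux",
    "facet_side_cells",
    "apply_dirichlet",
]

_QDEG = 5


# --------------------------------------------------------------------- volume
def _vol_setup(test: FunctionSpace, trial: FunctionSpace, qdeg=_QDEG):
    if test.mesh is not trial.mesh or not np.array_equal(test.cells, trial.cells):
        raise ValueError("volume forms require test/trial spaces on the same cells")
    mesh = test.mesh
    qp, qw = simplex_rule(mesh.dim, qdeg)
    F, invF, det = mesh.cell_jacobians()
    c = test.cells
    return mesh, qp, qw, F[c], invF[c], det[c]


def _phys_grads(space: FunctionSpace, qp, invF):
    g = space.tabulate_grad(qp)                    # (nq, nl, dref)
    return np.einsum("qlk,cki->cqli", g, invF)     # (nc, nq, nl, dim)


def _scatter(test_dofs, trial_dofs, local):
    """local: (nc, nl_test, nl_trial) -> COO triplets."""
    nc, a, b = local.shape
    rows = np.repeat(test_dofs, b, axis=1).reshape(-1)
    cols = np.tile(trial_dofs, (1, a)).reshape(-1)
    return rows, cols, local.reshape(-1)


def mass(test: FunctionSpace, trial: FunctionSpace, coeff: float = 1.0, qdeg=_QDEG):
    """(coeff * trial, test) over the common cells (scalar spaces)."""
    mesh, qp, qw, F, invF, det = _vol_setup(test, trial, qdeg)
    pt = test.tabulate(qp)
    pr = trial.tabulate(qp)
    local = coeff * np.einsum("q,c,qa,qb->cab", qw, det, pt, pr)
    return _scatter(test.cell_dofs, trial.cell_dofs, local)


def stiffness(test: FunctionSpace, trial: FunctionSpace, coeff: float = 1.0, qdeg=_QDEG):
    """(coeff * grad trial, grad test) (scalar spaces)."""
    mesh, qp, qw, F, invF, det = _vol_setup(test, trial, qdeg)
    Gt = _phys_grads(test, qp, invF)
    Gr = _phys_grads(trial, qp, invF)
    local = coeff * np.einsum("q,c,cqak,cqbk->cab", qw, det, Gt, Gr)
    return _scatter(test.cell_dofs, trial.cell_dofs, local)


def vector_mass(test: FunctionSpace, trial: FunctionSpace, coeff: float = 1.0, qdeg=_QDEG):
    """(coeff * trial, test) for vector spaces (component-diagonal)."""
    mesh, qp, qw, F, invF, det = _vol_setup(test, trial, qdeg)
    pt = test.tabulate(qp)
    pr = trial.tabulate(qp)
    m = coeff * np.einsum("q,c,qa,qb->cab", qw, det, pt, pr)  # scalar block
    d = test.ncomp
    nc, a, b = m.shape
    local = np.zeros((nc, a, d, b, d))
    for i in range(d):
        local[:, :, i, :, i] = m
    return _scatter(
        test.vector_cell_dofs(), trial.vector_cell_dofs(), local.reshape(nc, a * d, b * d)
    )


def elastic(test: FunctionSpace, trial: FunctionSpace, mu: float, qdeg=_QDEG):
    """2*mu*(eps(trial), eps(test)) for vector spaces."""
    mesh, qp, qw, F, invF, det = _vol_setup(test, trial, qdeg)
    Gt = _phys_grads(test, qp, invF)
    Gr = _phys_grads(trial, qp, invF)
    lap = np.einsum("q,c,cqak,cqbk->cab", qw, det, Gt, Gr)
    cross = np.einsum("q,c,cqaj,cqbi->cajbi", qw, det, Gt, Gr)
    d = test.ncomp
    nc, a, b = lap.shape
    local = mu * cross.transpose(0, 1, 4, 3, 2).copy()  # (c, a, i, b, j) = cross[c,a,j,b,i]
    for i in range(d):
        local[:, :, i, :, i] += mu * lap
    return _scatter(
        test.vector_cell_dofs(), trial.vector_cell_dofs(), local.reshape(nc, a * d, b * d)
    )


def div_coupling(test: FunctionSpace, trial: FunctionSpace, coeff: float = 1.0, qdeg=_QDEG):
    """(coeff * div(trial_vector), test_scalar)."""
    mesh, qp, qw, F, invF, det = _vol_setup(test, trial, qdeg)
    pt = test.tabulate(qp)                          # (nq, nl_t)
    Gr = _phys_grads(trial, qp, invF)               # (nc, nq, nl_r, dim)
    loc = coeff * np.einsum("q,c,qa,cqbj->cabj", qw, det, pt, Gr)
    nc, a, b, d = loc.shape
    rows = np.repeat(test.cell_dofs, b * d, axis=1).reshape(-1)
    cols = np.tile(trial.vector_cell_dofs(), (1, a)).reshape(-1)
    return rows, cols, loc.reshape(nc, a, b * d).reshape(-1)


def volume_load(space: FunctionSpace, fn, qdeg=_QDEG) -> np.ndarray:
    """(f, v) with f a callable of physical coordinates.

    For vector spaces fn(points) must return (n, ncomp).
    """
    mesh = space.mesh
    qp, qw = simplex_rule(mesh.dim, qdeg)
    F, invF, det = mesh.cell_jacobians()
    c = space.cells
    p0 = mesh.points[mesh.cells[c, 0]]
    phys = p0[:, None, :] + np.einsum("cij,qj->cqi", F[c], qp)
    fv = np.asarray(fn(phys.reshape(-1, mesh.dim)), dtype=float)
    phi = space.tabulate(qp)                        # (nq, nl)
    out = np.zeros(space.ndof)
    if space.ncomp == 1:
        fv = fv.reshape(len(c), len(qw))
        loc = np.einsum("q,c,cq,qa->ca", qw, det[c], fv, phi)
        np.add.at(out, space.cell_dofs, loc)
    else:
        fv = fv.reshape(len(c), len(qw), space.ncomp)
        loc = np.einsum("q,c,cqi,qa->cai", qw, det[c], fv, phi)
        np.add.at(out, space.vector_cell_dofs(), loc.reshape(len(c), -1))
    return out


# --------------------------------------------------------------------- facets
def facet_side_cells(mesh, facet_ids, space: FunctionSpace) -> np.ndarray:
    """For each facet, the adjacent cell belonging to the space's subdomain."""
    fc = mesh.facet_cells[np.asarray(facet_ids, dtype=np.int64)]
    member = np.zeros(mesh.num_cells + 1, dtype=bool)
    member[space.cells] = True
    pick0 = member[fc[:, 0]]
    out = np.where(pick0, fc[:, 0], fc[:, 1])
    if np.any(out < 0) or not member[out].all():
        raise ValueError("facet has no adjacent cell inside the space's subdomain")
    return out


class FacetContext:
    """Shared per-facet quadrature data: physical points, weights, normals."""

    def __init__(self, mesh, facet_ids, orient_cells, qdeg=_QDEG):
        self.mesh = mesh
        self.facet_ids = np.asarray(facet_ids, dtype=np.int64)
        fdim = mesh.dim - 1
        qp, qw = simplex_rule(fdim, qdeg)
        self.qp = qp                                      # facet reference points
        fv = mesh.points[mesh.facets[self.facet_ids]]     # (nf, dim, dim)
        E = fv[:, 1:, :] - fv[:, :1, :]                   # (nf, fdim, dim)
        self.phys = fv[:, :1, :] + np.einsum("qk,fkd->fqd", qp, E)  # (nf, nq, dim)
        area = mesh.facet_areas(self.facet_ids)
        self.w = qw[None, :] * (area[:, None] * factorial(fdim))    # (nf, nq)
        self.normals = mesh.facet_normals(self.facet_ids, orient_cells)
        self.areas = area

    def trace(self, space: FunctionSpace, grad: bool = False):
        """Tabulate space basis (or physical gradients) at the facet quad points.

        Returns (values, dofs): values (nf, nq, nloc[, dim]), dofs (nf, nloc).
        """
        mesh = self.mesh
        side = facet_side_cells(mesh, self.facet_ids, space)
        F, invF, _ = mesh.cell_jacobians()
        p0 = mesh.points[mesh.cells[side, 0]]
        ref = np.einsum("fij,fqj->fqi", invF[side], self.phys - p0[:, None, :])
        # map side cell ids -> rows in space.cells
        pos = np.full(mesh.num_cells, -1, dtype=np.int64)
        pos[space.cells] = np.arange(len(space.cells))
        dofs = space.cell_dofs[pos[side]]
        if grad:
            g = space.tabulate_grad(ref)                   # (nf, nq, nl, dref)
            vals = np.einsum("fqlk,fki->fqli", g, invF[side])
        else:
            vals = space.tabulate(ref)                     # (nf, nq, nl)
        return vals, dofs


def facet_vec_normal_scalar(ctx: FacetContext, V: FunctionSpace, Q: FunctionSpace,
                            coeff: float = 1.0):
    """coeff * int_F (v . n) q  with v in vector space V, q in scalar space Q.

    Rows are V dofs, cols are Q dofs (transpose for the adjoint term).
    """
    pv, vdofs = ctx.trace(V)
    pq, qdofs = ctx.trace(Q)
    loc = coeff * np.einsum("fq,fqa,fi,fqb->faib", ctx.w, pv, ctx.normals, pq)
    nf, a, d, b = loc.shape
    vd = (vdofs[:, :, None] * V.ncomp + np.arange(V.ncomp)[None, None, :]).reshape(nf, -1)
    rows = np.repeat(vd, b, axis=1).reshape(-1)
    cols = np.tile(qdofs, (1, a * d)).reshape(-1)
    return rows, cols, loc.reshape(-1)


def facet_tangential(ctx: FacetContext, V1: FunctionSpace, V2: FunctionSpace,
                     coeff: float = 1.0):
    """coeff * int_F (P_t v1) . (P_t v2) with P_t = I - n n^T.

    Rows are V1 dofs, cols V2 dofs (each from its own side of the facet).
    """
    p1, d1 = ctx.trace(V1)
    p2, d2 = ctx.trace(V2)
    n = ctx.normals
    d = V1.ncomp
    proj = np.eye(d)[None, :, :] - np.einsum("fi,fj->fij", n, n)
    loc = coeff * np.einsum("fq,fqa,fqb,fij->faibj", ctx.w, p1, p2, proj)
    nf, a, _, b, _ = loc.shape
    vd1 = (d1[:, :, None] * d + np.arange(d)[None, None, :]).reshape(nf, -1)
    vd2 = (d2[:, :, None] * d + np.arange(d)[None, None, :]).reshape(nf, -1)
    rows = np.repeat(vd1, b * d, axis=1).reshape(-1)
    cols = np.tile(vd2, (1, a * d)).reshape(-1)
    return rows, cols, loc.reshape(nf, a * d, b * d).reshape(-1)


def facet_tangential_explicit(ctx: FacetContext, V1: FunctionSpace, V2: FunctionSpace,
                              tangents: np.ndarray, coeff: float = 1.0):
    """Same as facet_tangential but with explicitly supplied tangent vectors.

    tangents: (ntan, dim) constant tangent frame (flat facets).
    """
    p1, d1 = ctx.trace(V1)
    p2, d2 = ctx.trace(V2)
    d = V1.ncomp
    proj = np.einsum("ti,tj->ij", tangents, tangents)[None, :, :] * np.ones((len(ctx.facet_ids), 1, 1))
    loc = coeff * np.einsum("fq,fqa,fqb,fij->faibj", ctx.w, p1, p2, proj)
    nf, a, _, b, _ = loc.shape
    vd1 = (d1[:, :, None] * d + np.arange(d)[None, None, :]).reshape(nf, -1)
    vd2 = (d2[:, :, None] * d + np.arange(d)[None, None, :]).reshape(nf, -1)
    rows = np.repeat(vd1, b * d, axis=1).reshape(-1)
    cols = np.tile(vd2, (1, a * d)).reshape(-1)
    return rows, cols, loc.reshape(nf, a * d, b * d).reshape(-1)


def facet_normal_load(ctx: FacetContext, V: FunctionSpace, pfn) -> np.ndarray:
    """int_F p (v . n) with p a scalar (constant or callable of coordinates)."""
    pv, vdofs = ctx.trace(V)
    if callable(pfn):
        pvals = np.asarray(pfn(ctx.phys.reshape(-1, ctx.mesh.dim))).reshape(ctx.w.shape)
    else:
        pvals = float(pfn) * np.ones_like(ctx.w)
    loc = np.einsum("fq,fq,fqa,fi->fai", ctx.w, pvals, pv, ctx.normals)
    nf, a, d = loc.shape
    vd = (vdofs[:, :, None] * V.ncomp + np.arange(V.ncomp)[None, None, :]).reshape(nf, -1)
    out = np.zeros(V.ndof)
    np.add.at(out, vd, loc.reshape(nf, -1))
    return out


def facet_flux(ctx: FacetContext, V: FunctionSpace, vec: np.ndarray) -> float:
    """int_F u . n for a discrete vector field u given by dof vector vec."""
    pv, vdofs = ctx.trace(V)
    vals = vec.reshape(-1, V.ncomp)[vdofs]            # (nf, nl, ncomp)
    u = np.einsum("fqa,fai->fqi", pv, vals)
    return float(np.einsum("fq,fqi,fi->", ctx.w, u, ctx.normals))


def facet_scalar_gradient_normal_flux(ctx: FacetContext, Q: FunctionSpace,
                                      vec: np.ndarray) -> float:
    """int_F grad(p) . n for a discrete scalar field p (side-cell gradient)."""
    gq, qdofs = ctx.trace(Q, grad=True)               # (nf, nq, nl, dim)
    gr = np.einsum("fqli,fl->fqi", gq, vec[qdofs])
    return float(np.einsum("fq,fqi,fi->", ctx.w, gr, ctx.normals))


def facet_trace_normal_vec(ctx: FacetContext, L, V: FunctionSpace,
                           coeff: float = 1.0):
    """coeff * int_F (v . n) mu with mu in a facet TraceSpace.

    Rows are trace-space dofs (constraint rows), cols are V dofs.
    """
    pv, vdofs = ctx.trace(V)                      # (nf, nq, nl), (nf, nl)
    if not np.array_equal(L.facet_ids, ctx.facet_ids):
        raise ValueError("trace space and context must use the same facets")
    pmu = L.tabulate(ctx.qp)                      # (nq, dim)
    loc = coeff * np.einsum("fq,qm,fqa,fi->fmai", ctx.w, pmu, pv, ctx.normals)
    nf, m, a, d = loc.shape
    vd = (vdofs[:, :, None] * V.ncomp + np.arange(V.ncomp)[None, None, :]).reshape(nf, -1)
    rows = np.repeat(L.facet_dofs, a * d, axis=1).reshape(-1)
    cols = np.tile(vd, (1, m)).reshape(-1)
    return rows, cols, loc.reshape(nf, m, a * d).reshape(-1)


def facet_trace_grad_normal(ctx: FacetContext, L, Q: FunctionSpace,
                            coeff: float = 1.0):
    """coeff * int_F (grad q . n) mu (side-cell gradient of a scalar space)."""
    gq, qdofs = ctx.trace(Q, grad=True)           # (nf, nq, nl, dim)
    pmu = L.tabulate(ctx.qp)
    loc = coeff * np.einsum("fq,qm,fqai,fi->fma", ctx.w, pmu, gq, ctx.normals)
    nf, m, a = loc.shape
    rows = np.repeat(L.facet_dofs, a, axis=1).reshape(-1)
    cols = np.tile(qdofs, (1, m)).reshape(-1)
    return rows, cols, loc.reshape(-1)


# ------------------------------------------------------------------ dirichlet
def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray,
                    values: np.ndarray):
    """Eliminate Dirichlet dofs symmetrically (rows and columns).

    Modifies b in place; returns the modified matrix (csr).
    """
    dofs = np.asarray(dofs, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[dofs] = True
    x0 = np.zeros(n)
    x0[dofs] = values
    b -= A @ x0
    b[dofs] = values
    keep = sp.diags((~mask).astype(float))
    A = keep @ A @ keep
    A = A.tolil()
    A[dofs, dofs] = 1.0
    return A.tocsr()
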