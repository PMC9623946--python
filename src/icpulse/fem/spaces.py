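"""Continuous Lagrange P1/P2 spaces restricted to subdomains."""

from __future__ import annotations

import numpy as np

from icpulse.fem.mesh import SimplexMesh, local_edges

__all__ = ["FunctionSpace"]


def _p1_values(ref_pts: np.ndarray) -> np.ndarray:
    lam0 = 1.0 - ref_pts.sum(axis=-1, keepdims=True)
    return np.concatenate([lam0, ref_pts], axis=-1)


def _p1_grads(ref_pts: np.ndarray, dim: int) -> np.ndarray:
    n = ref_pts.shape[:-1]
    g = np.zeros(n + (dim + 1, dim))
    g[..., 0, :] = -1.0
    for i in range(dim):
        g[..., i + 1, i] = 1.0
    return g


def _p2_values(ref_pts: np.ndarray, dim: int) -> np.ndarray:
    lam = _p1_values(ref_pts)                   # (..., dim+1)
    verts = lam * (2.0 * lam - 1.0)
    edge = []
    for (i, j) in local_edges(dim):
        edge.append(4.0 * lam[..., i] * lam[..., j])
    return np.concatenate([verts, np.stack(edge, axis=-1)], axis=-1)


def _p2_grads(ref_pts: np.ndarray, dim: int) -> np.ndarray:
    lam = _p1_values(ref_pts)
    glam = _p1_grads(ref_pts, dim)              # (..., dim+1, dim)
    parts = []
    for i in range(dim + 1):
        parts.append((4.0 * lam[..., i : i + 1] - 1.0) * glam[..., i, :])
    for (i, j) in local_edges(dim):
        parts.append(
            4.0 * (lam[..., i : i + 1] * glam[..., j, :] + lam[..., j : j + 1] * glam[..., i, :])
        )
    return np.stack(parts, axis=-2)             # (..., nloc, dim)


class FunctionSpace:
    """P1 or P2 (vector-valued) Lagrange space on a set of mesh cells.

    Degrees of freedom are vertex values (P1) plus edge-midpoint values (P2),
    restricted to the entities of the given subdomain cells.  Vector spaces
    interleave components: global dof = scalar_dof * ncomp + component.
    """

    def __init__(self, mesh: SimplexMesh, degree: int, cells=None, ncomp: int = 1):
        if degree not in (1, 2):
            raise ValueError("only P1 and P2 are supported")
        self.mesh = mesh
        self.degree = degree
        self.ncomp = ncomp
        if cells is None:
            cells = np.arange(mesh.num_cells)
        self.cells = np.asarray(cells, dtype=np.int64)
        dim = mesh.dim
        conn = mesh.cells[self.cells]           # (nc, dim+1)
        used_verts = np.unique(conn)
        self.vertex_map = np.full(mesh.num_points, -1, dtype=np.int64)
        self.vertex_map[used_verts] = np.arange(len(used_verts))
        coords = [mesh.points[used_verts]]
        cell_dofs = [self.vertex_map[conn]]
        self._num_vert_dofs = len(used_verts)
        if degree == 2:
            ce = mesh.cell_edges[self.cells]
            used_edges = np.unique(ce)
            self.edge_map = np.full(mesh.num_edges, -1, dtype=np.int64)
            self.edge_map[used_edges] = len(used_verts) + np.arange(len(used_edges))
            coords.append(mesh.points[mesh.edges[used_edges]].mean(axis=1))
            cell_dofs.append(self.edge_map[ce])
        else:
            self.edge_map = None
        self.cell_dofs = np.concatenate(cell_dofs, axis=1)  # scalar dofs per cell
        self.dof_coords = np.concatenate(coords, axis=0)    # (ndof_scalar, dim)
        self.ndof_scalar = len(self.dof_coords)
        self.ndof = self.ndof_scalar * ncomp
        self.nloc_scalar = self.cell_dofs.shape[1]

    # ------------------------------------------------------------ tabulation
    def tabulate(self, ref_pts: np.ndarray) -> np.ndarray:
        """Scalar shape function values at reference points (..., nloc)."""
        ref_pts = np.asarray(ref_pts, dtype=float)
        if self.degree == 1:
            return _p1_values(ref_pts)
        return _p2_values(ref_pts, self.mesh.dim)

    def tabulate_grad(self, ref_pts: np.ndarray) -> np.ndarray:
        """Reference gradients of scalar shape functions (..., nloc, dim)."""
        ref_pts = np.asarray(ref_pts, dtype=float)
        if self.degree == 1:
            return _p1_grads(ref_pts, self.mesh.dim)
        return _p2_grads(ref_pts, self.mesh.dim)

    # ------------------------------------------------------------------ dofs
    def vector_cell_dofs(self) -> np.ndarray:
        """(nc, nloc_scalar*ncomp) global dofs, component-interleaved."""
        sd = self.cell_dofs
        if self.ncomp == 1:
            return sd
        out = sd[:, :, None] * self.ncomp + np.arange(self.ncomp)[None, None, :]
        return out.reshape(len(sd), -1)

    def facet_scalar_dofs(self, facet_ids) -> np.ndarray:
        """Unique scalar dofs whose nodes lie on the given facets."""
        fv = self.mesh.facets[np.asarray(facet_ids, dtype=np.int64)]
        dofs = [self.vertex_map[np.unique(fv)]]
        if self.degree == 2:
            # edges of a facet: all vertex pairs within the facet
            dim = self.mesh.dim
            pairs = []
            if dim == 2:
                pairs.append(np.sort(fv, axis=1))
            else:
                for (i, j) in ((0, 1), (0, 2), (1, 2)):
                    pairs.append(np.sort(fv[:, [i, j]], axis=1))
            allp = np.unique(np.concatenate(pairs, axis=0), axis=0)
            # map vertex pairs -> edge ids via searchsorted on mesh.edges
            def pack(a):
                a = np.ascontiguousarray(a)
                return a.view([("", a.dtype)] * a.shape[1]).ravel()
            pos = np.searchsorted(pack(self.mesh.edges), pack(allp))
            dofs.append(self.edge_map[pos])
        out = np.unique(np.concatenate(dofs))
        if np.any(out < 0):
            raise ValueError("facet dofs outside the space's subdomain")
        return out

    def boundary_scalar_dofs(self, tags) -> np.ndarray:
        """Scalar dofs on facets carrying any of the given tags."""
        tags = np.atleast_1d(tags)
        mask = np.isin(self.mesh.facet_tags, tags)
        fids = np.nonzero(mask)[0]
        if len(fids) == 0:
            return np.zeros(0, dtype=np.int64)
        return self.facet_scalar_dofs(fids)

    # ---------------------------------------------------------- interpolation
    def interpolate(self, fn) -> np.ndarray:
        """Dof vector of the nodal interpolant of a callable fn(points)->values.

        For vector spaces fn must return (n, ncomp).
        """
        vals = np.asarray(fn(self.dof_coords), dtype=float)
        if self.ncomp == 1:
            return vals.reshape(self.ndof)
        if vals.shape != (self.ndof_scalar, self.ncomp):
            raise ValueError(f"expected shape {(self.ndof_scalar, self.ncomp)}, got {vals.shape}")
        return vals.reshape(self.ndof)

    # ------------------------------------------------------------- evaluation
    def eval_at_points(self, vec: np.ndarray, pts) -> np.ndarray:
        """Evaluate a dof vector at physical points inside the subdomain."""
        pts = np.atleast_2d(pts)
        cells, ref = self.mesh.locate_points(pts, candidate_cells=self.cells)
        if np.any(cells < 0):
            raise ValueError("point(s) outside the space's subdomain")
        # local index of each cell within self.cells
        order = {c: i for i, c in enumerate(self.cells)}
        loc = np.array([order[c] for c in cells])
        phi = self.tabulate(ref)                        # (npts, nloc)
        dofs = self.cell_dofs[loc]                      # (npts, nloc)
        if self.ncomp == 1:
            return np.einsum("pl,pl->p", phi, vec[dofs])
        vals = vec.reshape(-1, self.ncomp)[dofs]        # (npts, nloc, ncomp)
        return np.einsum("pl,plc->pc", phi, vals)

    # ---------------------------------------------------------------- errors
    def l2_error(self, vec: np.ndarray, exact_fn, qdeg: int = 6) -> float:
        """L2 norm of (u_h - exact) over the subdomain cells."""
        from icpulse.fem.quadrature import simplex_rule

        mesh = self.mesh
        qp, qw = simplex_rule(mesh.dim, qdeg)
        F, _, det = mesh.cell_jacobians()
        p0 = mesh.points[mesh.cells[self.cells, 0]]
        phys = p0[:, None, :] + np.einsum("cij,qj->cqi", F[self.cells], qp)
        phi = self.tabulate(qp)                         # (nq, nloc)
        dofs = self.cell_dofs
        if self.ncomp == 1:
            uh = np.einsum("ql,cl->cq", phi, vec[dofs])
            ue = np.asarray(exact_fn(phys.reshape(-1, mesh.dim))).reshape(uh.shape)
            diff2 = (uh - ue) ** 2
        else:
            vals = vec.reshape(-1, self.ncomp)[dofs]    # (nc, nloc, ncomp)
            uh = np.einsum("ql,clk->cqk", phi, vals)
            ue = np.asarray(exact_fn(phys.reshape(-1, mesh.dim))).reshape(uh.shape)
            diff2 = ((uh - ue) ** 2).sum(axis=-1)
        return float(np.sqrt(np.einsum("cq,q,c->", diff2, qw, det[self.cells])))
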