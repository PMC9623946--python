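"""Tagged simplicial meshes (triangles in 2D, tetrahedra in 3D).

A mesh carries integer cell tags (subdomains) and integer facet tags
(boundary segments and interfaces).  Facets are (dim-1)-simplices identified
by their sorted vertex tuple.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SimplexMesh", "local_edges", "local_facets"]


def local_edges(dim: int) -> list[tuple[int, int]]:
    """Local vertex index pairs defining the cell edges (fixed ordering)."""
    if dim == 2:
        return [(0, 1), (0, 2), (1, 2)]
    if dim == 3:
        return [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    raise ValueError(f"unsupported dimension {dim}")


def local_facets(dim: int) -> list[tuple[int, ...]]:
    """Local vertex index tuples of the cell facets (facet i opposite vertex i)."""
    if dim == 2:
        return [(1, 2), (0, 2), (0, 1)]
    if dim == 3:
        return [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    raise ValueError(f"unsupported dimension {dim}")


class SimplexMesh:
    """Simplicial mesh with cell and facet tags.

    Parameters
    ----------
    points : (n_points, dim) float array
        Vertex coordinates (meters).
    cells : (n_cells, dim+1) int array
        Cell connectivity.
    cell_tags : (n_cells,) int array
        Subdomain id per cell.
    """

    def __init__(self, points, cells, cell_tags=None):
        self.points = np.ascontiguousarray(points, dtype=float)
        self.cells = np.ascontiguousarray(cells, dtype=np.int64)
        self.dim = self.points.shape[1]
        if self.cells.shape[1] != self.dim + 1:
            raise ValueError("cells must have dim+1 vertices per cell")
        if cell_tags is None:
            cell_tags = np.zeros(len(self.cells), dtype=np.int64)
        self.cell_tags = np.asarray(cell_tags, dtype=np.int64)
        if len(self.cell_tags) != len(self.cells):
            raise ValueError("one tag per cell required")
        self._build_entities()
        self.facet_tags = np.zeros(self.num_facets, dtype=np.int64)
        self._geometry_cache: dict = {}

    # ------------------------------------------------------------------ build
    def _build_entities(self) -> None:
        dim, cells = self.dim, self.cells
        # Edges (unique sorted vertex pairs) and cell->edge map.
        le = np.array(local_edges(dim))
        pairs = cells[:, le]                     # (nc, nle, 2)
        pairs = np.sort(pairs, axis=2)
        flat = pairs.reshape(-1, 2)
        edges, inv = np.unique(flat, axis=0, return_inverse=True)
        self.edges = edges
        self.cell_edges = inv.reshape(len(cells), len(le))
        # Facets (unique sorted vertex (dim)-tuples) and adjacency.
        lf = np.array(local_facets(dim))
        fv = cells[:, lf]                        # (nc, nlf, dim)
        fv = np.sort(fv, axis=2)
        flatf = fv.reshape(-1, dim)
        facets, invf, counts = np.unique(
            flatf, axis=0, return_inverse=True, return_counts=True
        )
        self.facets = facets                     # (nf, dim) sorted vertex ids
        self.cell_facets = invf.reshape(len(cells), len(lf))
        nf = len(facets)
        facet_cells = np.full((nf, 2), -1, dtype=np.int64)
        # fill adjacency: iterate over (cell, local facet) pairs
        order = np.argsort(invf, kind="stable")
        cell_of = np.repeat(np.arange(len(cells)), len(lf))[order]
        fid = invf[order]
        starts = np.searchsorted(fid, np.arange(nf))
        ends = np.searchsorted(fid, np.arange(nf), side="right")
        facet_cells[:, 0] = cell_of[starts]
        two = counts == 2
        facet_cells[two, 1] = cell_of[ends[two] - 1]
        self.facet_cells = facet_cells
        self.boundary_facets = np.nonzero(counts == 1)[0]

    # ------------------------------------------------------------- properties
    @property
    def num_points(self) -> int:
        return len(self.points)

    @property
    def num_cells(self) -> int:
        return len(self.cells)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    @property
    def num_facets(self) -> int:
        return len(self.facets)

    # -------------------------------------------------------------- geometry
    def cell_jacobians(self):
        """Affine maps x = p0 + F x_ref: returns F (nc,d,d), invF, |det F|."""
        if "jac" not in self._geometry_cache:
            p = self.points[self.cells]          # (nc, d+1, d)
            F = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)  # (nc, d, d)
            det = np.linalg.det(F)
            if np.any(det <= 0):
                # orientation is normalized at construction time by callers;
                # tolerate negative determinants by using |det| in measures
                pass
            invF = np.linalg.inv(F)
            self._geometry_cache["jac"] = (F, invF, np.abs(det))
        return self._geometry_cache["jac"]

    def cell_volumes(self) -> np.ndarray:
        from math import factorial

        _, _, det = self.cell_jacobians()
        return det / factorial(self.dim)

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def facet_areas(self, facet_ids) -> np.ndarray:
        from math import factorial

        fv = self.points[self.facets[facet_ids]]   # (nf, dim, dim)
        e = fv[:, 1:, :] - fv[:, :1, :]            # (nf, dim-1, dim)
        if self.dim == 2:
            return np.linalg.norm(e[:, 0, :], axis=1)
        cross = np.cross(e[:, 0, :], e[:, 1, :])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def facet_normals(self, facet_ids, ref_cells) -> np.ndarray:
        """Unit normals on the given facets pointing OUT of `ref_cells`."""
        facet_ids = np.asarray(facet_ids)
        ref_cells = np.asarray(ref_cells)
        fv = self.points[self.facets[facet_ids]]
        e = fv[:, 1:, :] - fv[:, :1, :]
        if self.dim == 2:
            t = e[:, 0, :]
            n = np.stack([t[:, 1], -t[:, 0]], axis=1)
        else:
            n = np.cross(e[:, 0, :], e[:, 1, :])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        # orient: outward means pointing away from the ref cell centroid
        cent = self.cell_centroids()[ref_cells]
        fcent = fv.mean(axis=1)
        flip = np.einsum("fd,fd->f", n, fcent - cent) < 0
        n[flip] *= -1.0
        return n

    # ------------------------------------------------------------------ tags
    def tag_facets(self, facet_ids, tag: int) -> None:
        self.facet_tags[np.asarray(facet_ids, dtype=np.int64)] = tag

    def facets_with_tag(self, tag: int) -> np.ndarray:
        return np.nonzero(self.facet_tags == tag)[0]

    def find_facets(self, vertex_triples) -> np.ndarray:
        """Facet ids for given (sorted) vertex tuples."""
        key = np.sort(np.asarray(vertex_triples, dtype=np.int64), axis=1)
        # lexicographic search in self.facets
        nf = self.num_facets
        view = self.facets
        idx = np.zeros(len(key), dtype=np.int64)
        # use structured view for searchsorted
        def pack(a):
            return np.ascontiguousarray(a).view([("", a.dtype)] * a.shape[1]).ravel()
        pf = pack(view)
        pk = pack(key)
        pos = np.searchsorted(pf, pk)
        if np.any(pos >= nf) or np.any(pf[np.minimum(pos, nf - 1)] != pk):
            raise KeyError("some requested facets are not in the mesh")
        return pos

    def interface_facets(self, tag_a: int, tag_b: int) -> np.ndarray:
        """Interior facets whose two cells carry subdomain tags a and b."""
        fc = self.facet_cells
        interior = fc[:, 1] >= 0
        t0 = self.cell_tags[fc[interior, 0]]
        t1 = self.cell_tags[fc[interior, 1]]
        hit = ((t0 == tag_a) & (t1 == tag_b)) | ((t0 == tag_b) & (t1 == tag_a))
        return np.nonzero(interior)[0][hit]

    # -------------------------------------------------------- point location
    def locate_points(self, pts, candidate_cells=None, tol=1e-10):
        """Find a containing cell for each point (or -1).

        Returns (cell_ids, barycentric-ish reference coords (n, dim)).
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if candidate_cells is None:
            candidate_cells = np.arange(self.num_cells)
        F, invF, _ = self.cell_jacobians()
        p0 = self.points[self.cells[candidate_cells, 0]]
        iF = invF[candidate_cells]
        out_cells = np.full(len(pts), -1, dtype=np.int64)
        out_ref = np.zeros((len(pts), self.dim))
        for i, x in enumerate(pts):
            ref = np.einsum("cij,cj->ci", iF, x - p0)
            lam0 = 1.0 - ref.sum(axis=1)
            ok = (ref >= -tol).all(axis=1) & (lam0 >= -tol)
            hits = np.nonzero(ok)[0]
            if len(hits):
                out_cells[i] = candidate_cells[hits[0]]
                out_ref[i] = ref[hits[0]]
        return out_cells, out_ref
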