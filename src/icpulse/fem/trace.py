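"""P1 Lagrange-multiplier space on a set of facets (interface mortar space)."""

from __future__ import annotations

import numpy as np

from icpulse.fem.mesh import SimplexMesh

__all__ = ["TraceSpace"]


class TraceSpace:
    """Continuous P1 space on a facet set, with vertex dofs.

    Used for the interface multiplier that enforces normal-flux continuity
    between the free fluid and the poroelastic medium.
    """

    def __init__(self, mesh: SimplexMesh, facet_ids, degree: int = 1):
        """degree=1: continuous P1 on the facet set; degree=0 with one global
        dof: a single constant multiplier over the whole facet set."""
        self.mesh = mesh
        self.degree = degree
        self.facet_ids = np.asarray(facet_ids, dtype=np.int64)
        fv = mesh.facets[self.facet_ids]          # (nf, dim) vertex ids
        if degree == 1:
            used = np.unique(fv)
            self.vertex_map = np.full(mesh.num_points, -1, dtype=np.int64)
            self.vertex_map[used] = np.arange(len(used))
            self.facet_dofs = self.vertex_map[fv]     # (nf, dim)
            self.ndof = len(used)
            self.dof_coords = mesh.points[used]
        elif degree == 0:
            self.facet_dofs = np.zeros((len(self.facet_ids), 1), dtype=np.int64)
            self.ndof = 1
            self.dof_coords = mesh.points[fv].mean(axis=(0, 1))[None, :]
        else:
            raise ValueError("trace space degree must be 0 (global) or 1")

    def tabulate(self, ref_pts: np.ndarray) -> np.ndarray:
        """Facet shape functions at facet reference coordinates (..., ndof_loc)."""
        ref_pts = np.asarray(ref_pts, dtype=float)
        if self.degree == 0:
            return np.ones(ref_pts.shape[:-1] + (1,))
        lam0 = 1.0 - ref_pts.sum(axis=-1, keepdims=True)
        return np.concatenate([lam0, ref_pts], axis=-1)
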