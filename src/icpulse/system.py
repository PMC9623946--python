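"""Monolithic implicit-Euler step operator for the coupled Stokes-Biot system.

Unknowns at each time level: parenchyma displacement ``d`` (vector P2), pore
pressure ``p_p`` (P1), total pressure ``phi`` (P1) on the poroelastic
subdomain; CSF velocity ``u`` (vector P2) and fluid pressure ``p_f`` (P1) on
the CSF subdomain.  The interface coupling enforces normal-flux continuity,
momentum conservation, normal-stress balance and the Beavers-Joseph-Saffman
tangential slip condition; the tangential terms use the projector
``P_t = I - n n^T``.

The discrete system matrix is constant when ``dt`` and the coefficients are
constant, so the sparse LU factorization is computed once and reused; only
the right-hand side changes between steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from icpulse.fem import assemble as asm
from icpulse.fem.assemble import FacetContext
from icpulse.fem.spaces import FunctionSpace
from icpulse.fem.trace import TraceSpace
from icpulse.geometry import CellTag, DomainModel, FacetTag
from icpulse.params import MaterialParams

__all__ = [
    "FieldState",
    "DirichletBC",
    "StepOperator",
    "bjs_coefficient",
    "spinal_outlet_pressure",
]


def bjs_coefficient(params: MaterialParams) -> float:
    """BJS tangential friction coefficient gamma*mu_f/sqrt(kappa) [Pa s/m]."""
    if params.kappa <= 0:
        raise ValueError(f"permeability must be positive, got {params.kappa}")
    return params.gamma * params.mu_f / np.sqrt(params.kappa)


def spinal_outlet_pressure(dV_out: float, params: MaterialParams) -> float:
    """Exponential spinal compliance law p = p0 * 10^(dV_out / PVI) [Pa]."""
    return params.p0 * 10.0 ** (dV_out / params.PVI)


@dataclass
class FieldState:
    """All unknown fields at one time level plus the accumulated outflow.

    ``theta`` is the interface multiplier enforcing normal-flux continuity
    (a traction correction that vanishes for the exact solution).
    """

    d: np.ndarray
    p_p: np.ndarray
    phi: np.ndarray
    u: np.ndarray
    p_f: np.ndarray
    theta: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    dV_out: float = 0.0
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.d.copy(), self.p_p.copy(), self.phi.copy(),
                          self.u.copy(), self.p_f.copy(), self.theta.copy(),
                          self.dV_out, self.t)


@dataclass(frozen=True)
class DirichletBC:
    """Essential condition on a field over a set of facet tags.

    ``value`` is a constant or a callable ``value(points, t)`` returning
    per-node values ((n,) for scalars, (n, dim) for vector fields).
    """

    field: str
    tags: tuple
    value: object = 0.0


def _tosp(triples, shape):
    r, c, v = triples
    return sp.coo_matrix((v, (r, c)), shape=shape).tocsr()


class StepOperator:
    """Assembles and factorizes one implicit-Euler step of the coupled system.

    Parameters
    ----------
    domain : DomainModel
    params : MaterialParams
    dt : float
        Time step (ignored in steady mode).
    steady : bool
        Drop all time-derivative terms (verification / Stokes fixtures).
    bcs : list of DirichletBC, optional
        Defaults to the scenario conditions: d = 0 on SPINAL_CORD,
        u = 0 on SKULL.
    traction_tags : tuple of facet tags
        Boundary tags receiving a normal traction -p n (the outlet pressure
        is supplied per step).  Defaults to (SPINAL_SAS,).
    """

    FIELDS = ("d", "p_p", "phi", "u", "p_f", "theta")

    def __init__(self, domain: DomainModel, params: MaterialParams,
                 dt: float | None = None, steady: bool = False,
                 bcs: list | None = None,
                 traction_tags: tuple = (FacetTag.SPINAL_SAS,),
                 equilibrate: bool = True, flux_multiplier: bool = True,
                 multiplier_degree: int = 0):
        if not steady:
            if dt is None or dt <= 0:
                raise ValueError(f"transient mode requires dt > 0, got {dt}")
        if params.nu >= 0.5:
            raise ValueError("nu >= 0.5: incompressible solid not supported")
        self.domain = domain
        self.params = params
        self.dt = dt
        self.steady = steady
        self.equilibrate = equilibrate
        mesh = domain.mesh
        dim = mesh.dim
        par = domain.parenchyma_cells
        csf = domain.csf_cells
        self.has_solid = len(par) > 0
        self.has_fluid = len(csf) > 0

        spaces = {}
        if self.has_solid:
            spaces["d"] = FunctionSpace(mesh, 2, cells=par, ncomp=dim)
            spaces["p_p"] = FunctionSpace(mesh, 1, cells=par)
            spaces["phi"] = FunctionSpace(mesh, 1, cells=par)
        if self.has_fluid:
            spaces["u"] = FunctionSpace(mesh, 2, cells=csf, ncomp=dim)
            spaces["p_f"] = FunctionSpace(mesh, 1, cells=csf)
        self.spaces = spaces
        self._build_contexts_pre()
        # the flux multiplier is pinned through the d(t) coupling of the
        # constraint; the steady operator (verification fixtures) would be
        # singular with it, so it is a transient-only device
        self.flux_multiplier = flux_multiplier and not steady
        if self.has_interface and self.flux_multiplier:
            spaces["theta"] = TraceSpace(mesh, self.domain.interface_facets,
                                         degree=multiplier_degree)
        self.off = {}
        n = 0
        for f in self.FIELDS:
            if f in spaces:
                self.off[f] = n
                n += spaces[f].ndof
        self.N = n

        if bcs is None:
            bcs = []
            if self.has_solid:
                bcs.append(DirichletBC("d", (FacetTag.SPINAL_CORD,), 0.0))
            if self.has_fluid:
                bcs.append(DirichletBC("u", (FacetTag.SKULL,), 0.0))
        self.bcs = bcs
        self.traction_tags = tuple(traction_tags)

        self._build_contexts()
        self._assemble_matrix()
        self._assemble_fixed_vectors()
        self._prepare_dirichlet()
        self._lu = None
        self._smw = {}

    # ------------------------------------------------------------------ setup
    def _build_contexts_pre(self):
        mesh = self.domain.mesh
        iface = self.domain.interface_facets
        self.has_interface = self.has_solid and self.has_fluid and len(iface) > 0
        if self.has_interface:
            # normal points from the CSF into the parenchyma
            self.ictx = FacetContext(mesh, iface, self.domain.interface_orient_cells())

    def _build_contexts(self):
        mesh = self.domain.mesh
        self.tctx = {}
        for tag in self.traction_tags:
            fids = mesh.facets_with_tag(tag)
            if len(fids) == 0:
                continue
            self.tctx[tag] = FacetContext(mesh, fids, mesh.facet_cells[fids, 0])
        if FacetTag.SPINAL_SAS in self.traction_tags and FacetTag.SPINAL_SAS not in self.tctx:
            if self.has_fluid and self.domain.meta.get("fixture") is None:
                raise ValueError("outlet boundary SPINAL_SAS is empty; the fluid "
                                 "pressure level would be undetermined")

    def _assemble_matrix(self):
        p = self.params
        dt = self.dt
        idt = 0.0 if self.steady else 1.0 / dt
        beta = bjs_coefficient(p)
        S = self.spaces
        blocks = []  # (row_field, col_field, (r, c, v))

        if self.has_solid:
            Vd, Qp, Qphi = S["d"], S["p_p"], S["phi"]
            blocks.append(("d", "d", asm.elastic(Vd, Vd, p.mu_s)))
            r, c, v = asm.div_coupling(Qphi, Vd, 1.0)
            blocks.append(("d", "phi", (c, r, -v)))            # -int phi div w
            blocks.append(("phi", "d", asm.div_coupling(Qphi, Vd, p.lam)))
            blocks.append(("phi", "phi", asm.mass(Qphi, Qphi, 1.0)))
            blocks.append(("phi", "p_p", asm.mass(Qphi, Qp, -p.alpha)))
            blocks.append(("p_p", "p_p", asm.stiffness(Qp, Qp, p.kappa / p.mu_f)))
            if not self.steady:
                storage = p.c + p.alpha ** 2 / p.lam
                blocks.append(("p_p", "p_p", asm.mass(Qp, Qp, storage * idt)))
                blocks.append(("p_p", "phi", asm.mass(Qp, Qphi, -p.alpha / p.lam * idt)))

        if self.has_fluid:
            Vu, Qf = S["u"], S["p_f"]
            blocks.append(("u", "u", asm.elastic(Vu, Vu, p.mu_f)))
            r, c, v = asm.div_coupling(Qf, Vu, 1.0)
            blocks.append(("u", "p_f", (c, r, -v)))            # -int p_f div v
            blocks.append(("p_f", "u", (r, c, v)))
            if not self.steady:
                blocks.append(("u", "u", asm.vector_mass(Vu, Vu, p.rho_f * idt)))

        if self.has_interface:
            ctx = self.ictx
            Vd, Qp, Vu = S["d"], S["p_p"], S["u"]
            # normal-stress balance: -int p_p (w.n), +int p_p (v.n)
            blocks.append(("d", "p_p", asm.facet_vec_normal_scalar(ctx, Vd, Qp, -1.0)))
            blocks.append(("u", "p_p", asm.facet_vec_normal_scalar(ctx, Vu, Qp, +1.0)))
            # normal-flux continuity in the mass equation
            r, c, v = asm.facet_vec_normal_scalar(ctx, Vu, Qp, 1.0)
            blocks.append(("p_p", "u", (c, r, -v)))
            if not self.steady:
                r, c, v = asm.facet_vec_normal_scalar(ctx, Vd, Qp, 1.0)
                blocks.append(("p_p", "d", (c, r, idt * v)))
            # BJS tangential terms
            blocks.append(("u", "u", asm.facet_tangential(ctx, Vu, Vu, beta)))
            blocks.append(("d", "u", asm.facet_tangential(ctx, Vd, Vu, -beta)))
            if not self.steady:
                blocks.append(("u", "d", asm.facet_tangential(ctx, Vu, Vd, -beta * idt)))
                blocks.append(("d", "d", asm.facet_tangential(ctx, Vd, Vd, beta * idt)))
                # RHS operators (applied to the previous displacement)
                self._T_dd = _tosp(asm.facet_tangential(ctx, Vd, Vd, beta),
                                   (Vd.ndof, Vd.ndof))
                self._T_ud = _tosp(asm.facet_tangential(ctx, Vu, Vd, beta),
                                   (Vu.ndof, Vd.ndof))
                r, c, v = asm.facet_vec_normal_scalar(ctx, Vd, Qp, 1.0)
                self._C_pd = _tosp((c, r, v), (Qp.ndof, Vd.ndof))

        if self.has_interface and self.flux_multiplier:
            # normal-flux continuity constraint (interface multiplier):
            #   int_S (u - dd/dt + (kappa/mu_f) grad p_p) . n  mu = 0.
            # The multiplier acts back on the system as an interface normal
            # traction correction (+ on the fluid, - on the solid side); it
            # vanishes for the exact solution.
            ctx = self.ictx
            Vd, Qp, Vu = S["d"], S["p_p"], S["u"]
            L = S["theta"]
            tu = asm.facet_trace_normal_vec(ctx, L, Vu, 1.0)
            blocks.append(("theta", "u", tu))
            blocks.append(("u", "theta", (tu[1], tu[0], tu[2])))
            tp = asm.facet_trace_grad_normal(ctx, L, Qp, p.kappa / p.mu_f)
            blocks.append(("theta", "p_p", tp))
            td1 = asm.facet_trace_normal_vec(ctx, L, Vd, 1.0)
            blocks.append(("d", "theta", (td1[1], td1[0], -np.asarray(td1[2]))))
            blocks.append(("theta", "d", (td1[0], td1[1],
                                          -idt * np.asarray(td1[2]))))
            self._C_theta_d = _tosp(td1, (L.ndof, Vd.ndof))

        rows, cols, vals = [], [], []
        for rf, cf, (r, c, v) in blocks:
            rows.append(np.asarray(r) + self.off[rf])
            cols.append(np.asarray(c) + self.off[cf])
            vals.append(np.asarray(v, dtype=float))
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.N, self.N),
        ).tocsr()
        self.A = A

    def _assemble_fixed_vectors(self):
        p = self.params
        S = self.spaces
        if self.has_solid and not self.steady:
            Qp, Qphi = S["p_p"], S["phi"]
            storage = p.c + p.alpha ** 2 / p.lam
            self._M_store = _tosp(asm.mass(Qp, Qp, storage), (Qp.ndof, Qp.ndof))
            self._M_pphi = _tosp(asm.mass(Qp, Qphi, p.alpha / p.lam),
                                 (Qp.ndof, Qphi.ndof))
        if self.has_solid:
            self._ell_q = asm.volume_load(S["p_p"], lambda x: np.ones(len(x)))
        if self.has_fluid and not self.steady:
            Vu = S["u"]
            self._M_u = _tosp(asm.vector_mass(Vu, Vu, p.rho_f), (Vu.ndof, Vu.ndof))
        # traction load vectors: int_Gamma (v.n) ds per tag
        self._ell_trac = {}
        if self.has_fluid:
            for tag, ctx in self.tctx.items():
                self._ell_trac[tag] = asm.facet_normal_load(ctx, S["u"], 1.0)

    def _prepare_dirichlet(self):
        """Symmetric elimination with reusable column data for the RHS."""
        dofs = []
        self._bc_info = []
        for bc in self.bcs:
            if bc.field not in self.spaces:
                continue
            space = self.spaces[bc.field]
            tag_ids = [t if isinstance(t, int) else FacetTag.ids[t] for t in bc.tags]
            sdofs = space.boundary_scalar_dofs(tag_ids)
            if len(sdofs) == 0:
                continue
            if space.ncomp > 1:
                gdofs = (sdofs[:, None] * space.ncomp
                         + np.arange(space.ncomp)[None, :]).reshape(-1)
            else:
                gdofs = sdofs
            gdofs = gdofs + self.off[bc.field]
            coords = space.dof_coords[sdofs]
            self._bc_info.append((bc, space, gdofs, coords))
            dofs.append(gdofs)
        self.bc_dofs = (np.concatenate(dofs) if dofs
                        else np.zeros(0, dtype=np.int64))
        mask = np.zeros(self.N, dtype=bool)
        mask[self.bc_dofs] = True
        self._bc_mask = mask
        self._A_bc_cols = self.A.tocsc()[:, self.bc_dofs].tocsr()
        keep = sp.diags((~mask).astype(float))
        self.A_bc = (keep @ self.A @ keep + sp.diags(mask.astype(float))).tocsr()

    def _bc_values(self, t: float) -> np.ndarray:
        vals = np.zeros(self.N)
        for bc, space, gdofs, coords in self._bc_info:
            if callable(bc.value):
                v = np.asarray(bc.value(coords, t), dtype=float)
            else:
                v = np.full((len(coords), space.ncomp), float(bc.value))
            vals[gdofs] = v.reshape(-1)
        return vals[self.bc_dofs]

    def _factorize(self):
        if self._lu is None:
            A = self.A_bc.tocsc()
            if self.equilibrate:
                d = np.asarray(abs(A).max(axis=1).todense()).ravel()
                d[d == 0] = 1.0
                s = 1.0 / np.sqrt(d)
                self._scale = s
                S = sp.diags(s)
                A = (S @ A @ S).tocsc()
            else:
                self._scale = None
            self._lu = splu(A)

    # ------------------------------------------------------------------ state
    def rest_state(self) -> FieldState:
        """System at rest: d=u=0, p_p=p_f=p0, phi=alpha*p0, dV_out=0."""
        p = self.params
        S = self.spaces
        z = lambda f: np.zeros(S[f].ndof) if f in S else np.zeros(0)
        st = FieldState(z("d"), z("p_p"), z("phi"), z("u"), z("p_f"), z("theta"))
        if self.has_solid:
            st.p_p[:] = p.p0
            st.phi[:] = p.alpha * p.p0
        if self.has_fluid:
            st.p_f[:] = p.p0
        return st

    def join(self, st: FieldState) -> np.ndarray:
        x = np.zeros(self.N)
        for f in self.FIELDS:
            if f in self.spaces:
                x[self.off[f]: self.off[f] + self.spaces[f].ndof] = getattr(st, f)
        return x

    def split(self, x: np.ndarray, dV_out=0.0, t=0.0) -> FieldState:
        parts = {}
        for f in self.FIELDS:
            if f in self.spaces:
                parts[f] = x[self.off[f]: self.off[f] + self.spaces[f].ndof].copy()
            else:
                parts[f] = np.zeros(0)
        return FieldState(parts["d"], parts["p_p"], parts["phi"], parts["u"],
                          parts["p_f"], parts["theta"], dV_out=dV_out, t=t)

    # ------------------------------------------------------------------- step
    def assemble_rhs(self, prev: FieldState, t_new: float, g=0.0,
                     tractions: dict | None = None,
                     forcings: dict | None = None) -> np.ndarray:
        p = self.params
        idt = 0.0 if self.steady else 1.0 / self.dt
        b = np.zeros(self.N)
        S = self.spaces
        forcings = forcings or {}
        if self.has_solid:
            o = self.off["p_p"]
            npp = S["p_p"].ndof
            if callable(g):
                b[o:o + npp] += asm.volume_load(S["p_p"], g)
            elif g:
                b[o:o + npp] += float(g) * self._ell_q
            if not self.steady:
                b[o:o + npp] += idt * (self._M_store @ prev.p_p
                                       - self._M_pphi @ prev.phi)
            if "d" in forcings:
                b[self.off["d"]: self.off["d"] + S["d"].ndof] += \
                    asm.volume_load(S["d"], forcings["d"])
        if self.has_fluid:
            o = self.off["u"]
            nu_ = S["u"].ndof
            if not self.steady:
                b[o:o + nu_] += idt * (self._M_u @ prev.u)
            if "u" in forcings:
                b[o:o + nu_] += asm.volume_load(S["u"], forcings["u"])
            for tag, val in (tractions or {}).items():
                tag_id = tag if isinstance(tag, int) else FacetTag.ids[tag]
                if tag_id not in self.tctx:
                    continue
                if callable(val):
                    b[o:o + nu_] -= asm.facet_normal_load(self.tctx[tag_id],
                                                          S["u"], val)
                else:
                    b[o:o + nu_] -= float(val) * self._ell_trac[tag_id]
        if self.has_interface and not self.steady:
            b[self.off["d"]: self.off["d"] + S["d"].ndof] += idt * (self._T_dd @ prev.d)
            b[self.off["u"]: self.off["u"] + S["u"].ndof] -= idt * (self._T_ud @ prev.d)
            o = self.off["p_p"]
            b[o:o + S["p_p"].ndof] += idt * (self._C_pd @ prev.d)
            if self.flux_multiplier:
                o = self.off["theta"]
                b[o:o + S["theta"].ndof] -= idt * (self._C_theta_d @ prev.d)
        return b

    def _smw_vector(self, tag_id: int):
        """Cached solve of the outlet load vector (Sherman-Morrison data)."""
        if tag_id not in self._smw:
            ellg = np.zeros(self.N)
            o = self.off["u"]
            ellg[o:o + self.spaces["u"].ndof] = self._ell_trac[tag_id]
            ellg[self.bc_dofs] = 0.0
            if self._scale is not None:
                ells = self._scale * ellg
            else:
                ells = ellg
            z = self._lu.solve(ells)
            self._smw[tag_id] = (ells, z)
        return self._smw[tag_id]

    def step(self, prev: FieldState, t_new: float, g=0.0,
             tractions: dict | None = None,
             forcings: dict | None = None,
             traction_compliance: dict | None = None) -> FieldState:
        """Advance one implicit-Euler step (or solve the steady problem).

        ``traction_compliance`` maps a traction tag to the local pressure
        sensitivity k = dp/dV of its outflow condition; the resulting
        rank-one implicit term p = p_expl + k*dt*int(u.n) is applied via a
        Sherman-Morrison update so the factorization is still reused.
        Without it, a stiff outlet compliance (feedback gain k*C_storage
        above one) destabilizes the time-lagged outlet pressure.
        """
        self._factorize()
        b = self.assemble_rhs(prev, t_new, g=g, tractions=tractions,
                              forcings=forcings)
        vals = self._bc_values(t_new)
        b -= self._A_bc_cols @ vals
        b[self.bc_dofs] = vals
        bs = self._scale * b if self._scale is not None else b
        y = self._lu.solve(bs)
        for tag, k in (traction_compliance or {}).items():
            tag_id = tag if isinstance(tag, int) else FacetTag.ids[tag]
            if tag_id not in self._ell_trac or k == 0.0:
                continue
            sigma = k * (0.0 if self.steady else self.dt)
            ells, z = self._smw_vector(tag_id)
            y = y - sigma * z * (ells @ y) / (1.0 + sigma * (ells @ z))
        x = self._scale * y if self._scale is not None else y
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite values in the linear solve")
        return self.split(x, dV_out=prev.dV_out, t=t_new)

    # ------------------------------------------------------------ diagnostics
    def outflow_flux(self, st: FieldState, tag: int = FacetTag.SPINAL_SAS) -> float:
        """int_Gamma u.n with the outward normal (cranium -> spine positive)."""
        if tag not in self.tctx:
            return 0.0
        return asm.facet_flux(self.tctx[tag], self.spaces["u"], st.u)

    def stored_volume(self, st: FieldState, ref: FieldState) -> float:
        """Volume in the full storage terms (c p_p + alpha div d) since `ref`."""
        p = self.params
        storage = p.c + p.alpha ** 2 / p.lam
        return float(
            storage * (self._ell_q @ (st.p_p - ref.p_p))
            - (p.alpha / p.lam) * (self._ell_q @ (st.phi - ref.phi))
        )

    def stored_volume_c(self, st: FieldState, ref: FieldState) -> float:
        """Volume stored by the specific storage capacity alone, c*(p_p - ref)."""
        return float(self.params.c * (self._ell_q @ (st.p_p - ref.p_p)))

    def interface_normal_residual(self, st: FieldState, prev: FieldState) -> float:
        """Facet integral over the interface of (u - dd/dt + (k/mu) grad p_p).n."""
        if not self.has_interface:
            return 0.0
        p = self.params
        ctx = self.ictx
        r = asm.facet_flux(ctx, self.spaces["u"], st.u)
        if not self.steady:
            r -= asm.facet_flux(ctx, self.spaces["d"], (st.d - prev.d) / self.dt)
        r += (p.kappa / p.mu_f) * asm.facet_scalar_gradient_normal_flux(
            ctx, self.spaces["p_p"], st.p_p)
        return r
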