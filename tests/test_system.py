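"""Step-operator tests: rest state, interface terms, BJS, outlet, Stokes."""

import numpy as np
import pytest
import scipy.sparse as sp

from icpulse.fem import assemble as asm
from icpulse.fem.assemble import FacetContext
from icpulse.fem.spaces import FunctionSpace
from icpulse.geometry import (FacetTag, build_idealized, build_tube,
                              build_two_box_2d, build_two_box_3d)
from icpulse.params import MMHG_TO_PA, MaterialParams
from icpulse.system import (StepOperator, bjs_coefficient,
                            spinal_outlet_pressure)


class TestBJSCoefficient:
    def test_reference(self):
        p = MaterialParams()
        assert bjs_coefficient(p) == pytest.approx(0.8e-3 / 1e-8, rel=1e-12)

    def test_free_slip(self):
        assert bjs_coefficient(MaterialParams(gamma=0.0)) == 0.0

    def test_linearity(self):
        p1 = MaterialParams(gamma=1.0)
        p2 = MaterialParams(gamma=2.0)
        assert bjs_coefficient(p2) == pytest.approx(2 * bjs_coefficient(p1))

    def test_invalid_kappa(self):
        p = MaterialParams()
        object.__setattr__(p, "kappa", -1.0)
        with pytest.raises(ValueError):
            bjs_coefficient(p)


class TestSpinalOutletPressure:
    def test_initial(self):
        p = MaterialParams()
        assert spinal_outlet_pressure(0.0, p) == pytest.approx(
            4.5 * MMHG_TO_PA)

    def test_decade(self):
        p = MaterialParams()
        assert spinal_outlet_pressure(p.PVI, p) == pytest.approx(10 * p.p0)

    def test_derived_value(self):
        p = MaterialParams()
        val = spinal_outlet_pressure(0.8e-6, p) / MMHG_TO_PA
        assert val == pytest.approx(4.5 * 10 ** (0.8 / 3), rel=1e-12)
        assert val == pytest.approx(8.31, abs=0.01)

    def test_negative_volume_ok(self):
        p = MaterialParams()
        assert spinal_outlet_pressure(-p.PVI, p) == pytest.approx(p.p0 / 10)


class TestRestState:
    def test_two_box_rest_exact(self):
        dom = build_two_box_2d(4)
        p = MaterialParams()
        op = StepOperator(dom, p, dt=0.01)
        rest = op.rest_state()
        st = op.step(rest, 0.01, g=0.0)
        for f in ("d", "u"):
            assert np.abs(getattr(st, f)).max() < 1e-9
        assert np.abs(st.p_p - p.p0).max() < 1e-8 * p.p0
        assert np.abs(st.p_f - p.p0).max() < 1e-8 * p.p0
        assert np.abs(st.phi - p.alpha * p.p0).max() < 1e-8 * p.p0

    def test_idealized_rest_exact(self, ideal_domain):
        p = MaterialParams()
        op = StepOperator(ideal_domain, p, dt=0.02)
        rest = op.rest_state()
        st = rest
        for k in range(3):  # multiple steps stay at rest
            st = op.step(st, (k + 1) * 0.02, g=0.0,
                         tractions={FacetTag.SPINAL_SAS: p.p0})
        assert np.abs(st.d).max() < 1e-9
        assert np.abs(st.u).max() < 1e-9
        assert np.abs(st.p_f - p.p0).max() < 1e-7 * p.p0
        assert abs(op.outflow_flux(st)) < 1e-12

    def test_invalid_dt(self, ideal_domain):
        with pytest.raises(ValueError):
            StepOperator(ideal_domain, MaterialParams(), dt=0.0)

    def test_incompressible_rejected(self, ideal_domain):
        p = MaterialParams()
        object.__setattr__(p, "nu", 0.5)
        with pytest.raises(ValueError):
            StepOperator(ideal_domain, p, dt=0.01)


class TestBJSProjector:
    def test_projector_equals_explicit_tangents_3d(self):
        """P_t = I - n n^T against the explicit tau_1, tau_2 frame.

        On the flat z=0 interface of the two-box fixture the tangents are
        the coordinate directions; the assembled facet matrices must agree
        to round-off.
        """
        dom = build_two_box_3d(2)
        mesh = dom.mesh
        fids = mesh.facets_with_tag(FacetTag.INTERFACE)
        fc = mesh.facet_cells[fids]
        from icpulse.geometry import CellTag

        oc = np.where(mesh.cell_tags[fc[:, 0]] == CellTag.CSF,
                      fc[:, 0], fc[:, 1])
        ctx = FacetContext(mesh, fids, oc)
        csf = dom.csf_cells
        par = dom.parenchyma_cells
        Vu = FunctionSpace(mesh, 2, cells=csf, ncomp=3)
        Vd = FunctionSpace(mesh, 2, cells=par, ncomp=3)
        taus = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        for A, B in ((Vu, Vu), (Vd, Vu)):
            r1, c1, v1 = asm.facet_tangential(ctx, A, B, coeff=2.5)
            r2, c2, v2 = asm.facet_tangential_explicit(ctx, A, B, taus,
                                                       coeff=2.5)
            M1 = sp.coo_matrix((v1, (r1, c1)),
                               shape=(A.ndof, B.ndof)).toarray()
            M2 = sp.coo_matrix((v2, (r2, c2)),
                               shape=(A.ndof, B.ndof)).toarray()
            scale = np.abs(M1).max()
            assert np.abs(M1 - M2).max() < 1e-12 * max(scale, 1.0)

    def test_projector_equals_explicit_tangent_2d(self):
        dom = build_two_box_2d(3)
        mesh = dom.mesh
        fids = mesh.facets_with_tag(FacetTag.INTERFACE)
        ctx = FacetContext(mesh, fids, mesh.facet_cells[fids, 0])
        V = FunctionSpace(mesh, 2, cells=dom.csf_cells, ncomp=2)
        r1, c1, v1 = asm.facet_tangential(ctx, V, V)
        r2, c2, v2 = asm.facet_tangential_explicit(
            ctx, V, V, np.array([[1.0, 0.0]]))
        M1 = sp.coo_matrix((v1, (r1, c1)), shape=(V.ndof, V.ndof)).toarray()
        M2 = sp.coo_matrix((v2, (r2, c2)), shape=(V.ndof, V.ndof)).toarray()
        assert np.abs(M1 - M2).max() < 1e-12 * np.abs(M1).max()


class TestCouplingStructure:
    def test_interface_blocks_adjoint(self):
        """The off-diagonal interface normal-coupling blocks are adjoint
        pairs up to the time-derivative scalings."""
        dom = build_two_box_2d(3)
        p = MaterialParams()
        dt = 0.02
        op = StepOperator(dom, p, dt=dt)
        A = op.A.tocsr()
        o = op.off
        S = op.spaces
        sl = {f: slice(o[f], o[f] + S[f].ndof) for f in S}
        A_dp = A[sl["d"], sl["p_p"]].toarray()
        A_pd = A[sl["p_p"], sl["d"]].toarray()
        # A[p_p,d] = -(1/dt) * A[d,p_p]^T
        assert np.abs(A_pd + A_dp.T / dt).max() < 1e-10 * np.abs(A_pd).max()
        A_up = A[sl["u"], sl["p_p"]].toarray()
        A_pu = A[sl["p_p"], sl["u"]].toarray()
        assert np.abs(A_pu + A_up.T).max() < 1e-10 * np.abs(A_up).max()

    def test_no_volume_coupling_between_subdomains(self):
        """Parenchyma and CSF unknowns couple only through interface dofs."""
        dom = build_two_box_2d(3)
        op = StepOperator(dom, MaterialParams(), dt=0.02)
        A = op.A.tocsr()
        S = op.spaces
        # dofs of d away from the interface must have no u-columns
        iface = dom.mesh.facets_with_tag(FacetTag.INTERFACE)
        d_if = set(S["d"].facet_scalar_dofs(iface))
        u_off = op.off["u"]
        u_end = u_off + S["u"].ndof
        d_off = op.off["d"]
        scale = np.abs(A[d_off:d_off + S["d"].ndof, u_off:u_end].toarray()).max()
        for sdof in range(S["d"].ndof_scalar):
            if sdof in d_if:
                continue
            for comp in range(2):
                row = A[op.off["d"] + sdof * 2 + comp].toarray().ravel()
                # only round-off-level entries outside the interface dofs
                assert np.abs(row[u_off:u_end]).max() <= 1e-12 * scale


class TestStokesTube:
    def test_poiseuille(self):
        """Pressure-driven steady Stokes flow through a straight tube.

        Hagen-Poiseuille: Q = pi R^4 dp / (8 mu L) with R = 1.44 mm,
        L = 10 mm, dp = 1 Pa, mu = 0.8e-3 Pa s -> 2.11e-7 m^3/s.
        """
        p = MaterialParams()
        R, L, dp = 1.44e-3, 0.01, 1.0
        tube = build_tube(R, L, n_cross=8, n_axial=10)
        op = StepOperator(tube, p, steady=True,
                          traction_tags=(FacetTag.SPINAL_SAS,
                                         FacetTag.SPINAL_CORD))
        st = op.step(op.rest_state(), 0.0,
                     tractions={FacetTag.SPINAL_CORD: dp,
                                FacetTag.SPINAL_SAS: 0.0})
        Q = op.outflow_flux(st)
        Q_exact = np.pi * R ** 4 * dp / (8 * p.mu_f * L)
        assert Q == pytest.approx(2.11e-7, rel=0.05)
        assert Q == pytest.approx(Q_exact, rel=0.05)
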