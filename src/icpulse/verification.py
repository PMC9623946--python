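"""Manufactured-solution and convergence harness for the coupled discretization.

Cases are built symbolically on the two-box fixture (parenchyma below a flat
interface, CSF above).  The analytic fields are constructed to satisfy the
four interface conditions exactly on the flat interface; forcing terms are
obtained by substituting the fields into the strong equations.  Violating
ansatz choices raise at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sym

from icpulse.geometry import FacetTag, build_two_box_2d, build_two_box_3d
from icpulse.params import MaterialParams
from icpulse.system import DirichletBC, StepOperator

__all__ = [
    "ManufacturedCase",
    "ConstructionError",
    "verification_params",
    "build_case",
    "solve_case",
    "convergence_study",
    "fit_rate",
]


class ConstructionError(ValueError):
    """Ansatz violates the interface conditions."""


def verification_params() -> MaterialParams:
    """O(1) parameter set for verification runs (mu_s = lam = 1)."""
    return MaterialParams(E=2.5, nu=0.25, alpha=1.0, c=1.0, kappa=1.0,
                          mu_f=1.0, rho_f=1.0, rho_s=1.0, gamma=1.0,
                          PVI=1.0, p0=1.0)


@dataclass
class ManufacturedCase:
    """Closed-form space-time fields plus derived forcing terms."""

    dim: int
    steady: bool
    params: MaterialParams
    exact: dict       # name -> callable(points, t)
    forcing: dict     # 'd' / 'u' / 'g' -> callable(points, t)
    label: str = ""


def _lambdify(expr, coords, tsym, vector=False):
    f = sym.lambdify((*coords, tsym), expr, "numpy")

    def fn(points, t):
        args = [points[:, i] for i in range(len(coords))] + [t]
        val = f(*args)
        if vector:
            comps = [np.broadcast_to(np.asarray(v, dtype=float), (len(points),))
                     for v in val]
            return np.stack(comps, axis=1)
        return np.broadcast_to(np.asarray(val, dtype=float), (len(points),))

    return fn


def _interface_check(dim, p, d, u, p_p, phi, p_f, coords, tsym, steady):
    """Symbolic residuals of the interface conditions on the flat interface.

    The interface is {last coordinate = 0}; the normal points from the fluid
    (last coord > 0) into the parenchyma, i.e. n = -e_last.
    """
    z = coords[-1]
    n = sym.Matrix([0] * (dim - 1) + [-1])
    I = sym.eye(dim)
    eps = lambda v: (v.jacobian(sym.Matrix(coords))
                     + v.jacobian(sym.Matrix(coords)).T) / 2
    sigf = 2 * p.mu_f * eps(u) - p_f * I
    sigp = 2 * p.mu_s * eps(d) - phi * I
    dt_d = sym.Matrix([0] * dim) if steady else d.diff(tsym)
    gradpp = sym.Matrix([p_p.diff(c) for c in coords])
    residuals = []
    # normal flux continuity
    residuals.append(((u - dt_d + (p.kappa / p.mu_f) * gradpp).T * n)[0, 0])
    # traction continuity (vector)
    tb = sigf * n - sigp * n
    residuals.extend([tb[i, 0] for i in range(dim)])
    # normal stress balance
    residuals.append((-(n.T * sigf * n))[0, 0] - p_p)
    # BJS tangential condition
    beta = p.gamma * p.mu_f / sym.sqrt(p.kappa)
    Pt = I - n * n.T
    td = Pt * (sigf * n) + beta * Pt * (u - dt_d)
    residuals.extend([td[i, 0] for i in range(dim)])
    # numerical check of the residuals on the interface (robust with float
    # parameter values, where purely symbolic simplification can stall)
    rng = np.random.default_rng(1234)
    pts = rng.uniform(0.05, 0.95, size=(40, dim - 1))
    ts = np.array([0.0]) if steady else rng.uniform(0.0, 2.0, size=5)
    scale = 1.0 + max(p.mu_s, p.lam, p.mu_f, 1.0 / p.kappa)
    for r in residuals:
        r0 = sym.simplify(r.subs(z, 0))
        if r0 == 0:
            continue
        f = sym.lambdify((*coords[:-1], tsym), r0, "numpy")
        for t in ts:
            vals = np.asarray(f(*[pts[:, i] for i in range(dim - 1)], t),
                              dtype=float)
            if np.max(np.abs(vals)) > 1e-10 * scale:
                raise ConstructionError(
                    f"interface condition violated: residual {r0}")


def build_case(kind: str = "trig", dim: int = 2, steady: bool = False,
               params: MaterialParams | None = None,
               chi_factor: float = 2.0, pressure_scale: float = 1.0) -> ManufacturedCase:
    """Construct a manufactured case ('trig' or 'patch').

    The trig case is smooth (trigonometric, time-dependent unless steady);
    the patch case is quadratic in the vector fields and linear in the
    pressures, hence exactly representable in the P2/P1 spaces.

    ``chi_factor`` scales the fluid stream function relative to the solid
    one and ``pressure_scale`` the pore/fluid pressure base amplitude.  With
    balanced amplitudes the displacement picks up the known O(h^2+1/2)
    transfer of the P1 interface pressure trace; choosing both small (e.g.
    1.01 and 1e-2) makes that transfer subdominant so the study isolates
    the per-field element orders.
    """
    p = params or verification_params()
    if p.alpha != 1.0:
        raise ConstructionError("manufactured cases require alpha = 1")
    tsym = sym.symbols("t")
    if dim == 2:
        x, y = sym.symbols("x y")
        coords = (x, y)
    elif dim == 3:
        x, y, z3 = sym.symbols("x y z")
        coords = (x, y, z3)
    else:
        raise ValueError("dim must be 2 or 3")
    z = coords[-1]

    if kind == "trig":
        if dim != 2:
            raise ValueError("the trig case is two-dimensional")
        pi = sym.pi
        kf = sym.nsimplify(chi_factor, rational=True)
        ps = sym.nsimplify(pressure_scale, rational=True)
        eta = sym.sin(pi * x) * sym.cos(pi * z)       # solid stream function
        chi = kf * sym.sin(pi * x) * sym.cos(pi * z)  # fluid stream function
        ft = sym.Integer(1) if steady else sym.sin(tsym)
        gt = sym.Integer(1) if steady else sym.cos(tsym)
        d = ft * sym.Matrix([eta.diff(z), -eta.diff(x)])
        u = gt * sym.Matrix([chi.diff(z), -chi.diff(x)])
        a = sym.symbols("a_slope")
        P = sym.cos(pi * x) * (ps + a * z)
        p_p = gt * P
        # solve the normal-flux condition for the pressure slope a
        dt_d = sym.Matrix([0, 0]) if steady else d.diff(tsym)
        gradP = sym.Matrix([p_p.diff(c) for c in coords])
        n = sym.Matrix([0, -1])
        cond = ((u - dt_d + (p.kappa / p.mu_f) * gradP).T * n)[0, 0]
        cond0 = sym.simplify(cond.subs(z, 0))
        sol = sym.solve(sym.Eq(cond0 / (gt * sym.cos(pi * x)), 0), a)
        if not sol:
            raise ConstructionError("could not satisfy the normal-flux condition")
        p_p = p_p.subs(a, sol[0])
        p_f = gt * (2 * kf * p.mu_f * pi ** 2 * sym.cos(pi * x) * sym.sin(pi * z)
                    + ps * sym.cos(pi * x))
        label = "trig2d" + ("-steady" if steady else "")
    elif kind == "layered":
        # smooth fields varying only across the interface (shear-layer case):
        # free of the corner pollution of the full trig case, so it isolates
        # the per-field element orders
        if not steady:
            raise ValueError("the layered case is steady")
        om = 2 * sym.pi
        beta = p.gamma * p.mu_f / sym.sqrt(p.kappa)
        g1 = (p.mu_f * om / beta) * sym.cos(om * z) + sym.sin(om * z)
        f1 = (p.mu_f / p.mu_s) * sym.sin(om * z)
        ps = sym.nsimplify(pressure_scale, rational=True)
        P = ps * sym.cos(om * z)
        zero = [sym.Integer(0)] * (dim - 2)
        d = sym.Matrix([f1] + zero + [sym.Rational(1, 10)])
        u = sym.Matrix([g1] + zero + [0])
        p_p = P
        p_f = ps * (sym.cos(om * z) + z ** 2)
        label = f"layered{dim}d"
    elif kind == "patch":
        if not steady:
            raise ValueError("the patch case is steady")
        b = [sym.Rational(3, 10) + sym.Rational(i, 7) for i in range(dim - 1)]
        e = [sym.Rational(2, 10) + sym.Rational(i, 9) for i in range(dim - 1)]
        a_d = [sym.Rational(1, 10) * (i + 1) for i in range(dim - 1)]
        p_b = sym.Rational(1, 2)
        c_d = sym.Rational(1, 5)
        d = sym.Matrix([a_d[i] + b[i] * z ** 2 for i in range(dim - 1)] + [c_d])
        u_n = -(p.kappa / p.mu_f) * p_b
        u = sym.Matrix([e[i] * z ** 2 for i in range(dim - 1)] + [u_n])
        P = sym.Rational(1, 3) + p_b * z
        p_p = P
        p_f = sym.Rational(1, 3) + 0 * z
        label = f"patch{dim}d"
    else:
        raise ValueError(f"unknown case kind {kind!r}")

    div_d = sum(d[i, 0].diff(coords[i]) for i in range(dim))
    phi = p.alpha * p_p - p.lam * div_d
    _interface_check(dim, p, d, u, p_p, phi, p_f, coords, tsym, steady)

    # forcing terms by substitution into the strong equations
    I = sym.eye(dim)
    eps = lambda v: (v.jacobian(sym.Matrix(coords))
                     + v.jacobian(sym.Matrix(coords)).T) / 2
    div_tensor = lambda S: sym.Matrix(
        [sum(S[i, j].diff(coords[j]) for j in range(dim)) for i in range(dim)]
    )
    sigp = 2 * p.mu_s * eps(d) - phi * I
    f_d = -div_tensor(sigp)
    storage = (p.c + p.alpha ** 2 / p.lam)
    lap_pp = sum(p_p.diff(c, 2) for c in coords)
    g = (storage * p_p.diff(tsym) - (p.alpha / p.lam) * phi.diff(tsym)
         - (p.kappa / p.mu_f) * lap_pp)
    sigf = 2 * p.mu_f * eps(u) - p_f * I
    f_u = p.rho_f * u.diff(tsym) - div_tensor(sigf)
    div_u = sym.simplify(sum(u[i, 0].diff(coords[i]) for i in range(dim)))
    if div_u != 0:
        raise ConstructionError(f"fluid ansatz is not divergence free: {div_u}")

    exact = {
        "d": _lambdify(list(d), coords, tsym, vector=True),
        "u": _lambdify(list(u), coords, tsym, vector=True),
        "p_p": _lambdify(p_p, coords, tsym),
        "phi": _lambdify(phi, coords, tsym),
        "p_f": _lambdify(p_f, coords, tsym),
    }
    forcing = {
        "d": _lambdify(list(f_d), coords, tsym, vector=True),
        "u": _lambdify(list(f_u), coords, tsym, vector=True),
        "g": _lambdify(g, coords, tsym),
    }
    return ManufacturedCase(dim=dim, steady=steady, params=p, exact=exact,
                            forcing=forcing, label=label)


def _case_operator(case: ManufacturedCase, n: int, dt: float | None):
    dom = build_two_box_2d(n) if case.dim == 2 else build_two_box_3d(n)
    bcs = [
        DirichletBC("d", (FacetTag.SPINAL_CORD,),
                    lambda pts, t: case.exact["d"](pts, t)),
        DirichletBC("p_p", (FacetTag.SPINAL_CORD,),
                    lambda pts, t: case.exact["p_p"](pts, t)),
        DirichletBC("u", (FacetTag.SKULL,),
                    lambda pts, t: case.exact["u"](pts, t)),
    ]
    op = StepOperator(dom, case.params, dt=dt, steady=case.steady, bcs=bcs,
                      traction_tags=())
    return dom, op


def _solve_final(case: ManufacturedCase, n: int, dt: float | None,
                 t_end: float):
    """Run the case; return (operator, final state, final time)."""
    dom, op = _case_operator(case, n, dt)
    S = op.spaces

    def forcings_at(t):
        return {
            "d": lambda pts: case.forcing["d"](pts, t),
            "u": lambda pts: case.forcing["u"](pts, t),
        }

    if case.steady:
        new = op.step(op.rest_state(), 0.0,
                      g=lambda pts: case.forcing["g"](pts, 0.0),
                      forcings=forcings_at(0.0))
        return op, new, 0.0
    st = op.rest_state()
    for f in ("d", "u", "p_p", "phi", "p_f"):
        getattr(st, f)[:] = S[f].interpolate(
            lambda pts, f=f: case.exact[f](pts, 0.0))
    n_steps = int(round(t_end / dt))
    new = st
    for k in range(1, n_steps + 1):
        t = k * dt
        new = op.step(new, t, g=lambda pts: case.forcing["g"](pts, t),
                      forcings=forcings_at(t))
    return op, new, n_steps * dt


def solve_case(case: ManufacturedCase, n: int, dt: float | None = None,
               t_end: float = 0.5) -> dict:
    """Solve the case on an n-refined two-box mesh; return L2 errors per field.

    Steady cases are solved in one step; transient cases march implicit
    Euler from the interpolated exact initial state to t_end.
    """
    dom, op = _case_operator(case, n, dt)
    S = op.spaces

    def forcings_at(t):
        return {
            "d": lambda pts: case.forcing["d"](pts, t),
            "u": lambda pts: case.forcing["u"](pts, t),
        }

    if case.steady:
        st = op.rest_state()
        new = op.step(st, 0.0, g=lambda pts: case.forcing["g"](pts, 0.0),
                      forcings=forcings_at(0.0))
        t_fin = 0.0
    else:
        st = op.rest_state()
        for f in ("d", "u", "p_p", "phi", "p_f"):
            getattr(st, f)[:] = S[f].interpolate(
                lambda pts, f=f: case.exact[f](pts, 0.0))
        n_steps = int(round(t_end / dt))
        new = st
        for k in range(1, n_steps + 1):
            t = k * dt
            new = op.step(new, t, g=lambda pts: case.forcing["g"](pts, t),
                          forcings=forcings_at(t))
        t_fin = n_steps * dt
    errors = {}
    for f in ("d", "u", "p_p", "phi", "p_f"):
        errors[f] = S[f].l2_error(getattr(new, f),
                                  lambda pts, f=f: case.exact[f](pts, t_fin))
    return errors


def fit_rate(hs, errors) -> float:
    """Least-squares slope of log(error) vs log(h)."""
    hs = np.asarray(hs, dtype=float)
    errors = np.asarray(errors, dtype=float)
    mask = errors > 0
    return float(np.polyfit(np.log(hs[mask]), np.log(errors[mask]), 1)[0])


def convergence_study(case: ManufacturedCase, levels=(4, 8, 16),
                      dt: float | None = None, t_end: float = 0.5,
                      dts=None) -> dict:
    """Observed spatial (or temporal) convergence rates in the L2 norm.

    Spatial study: errors over mesh levels at fixed (or no) dt.
    Temporal study (dts given): fixed mesh `levels[-1]`, varying dt.
    Returns {'hs'/'dts', 'errors': {field: [..]}, 'rates': {field: slope}}.
    """
    fields = ("d", "u", "p_p", "phi", "p_f")
    out: dict = {"errors": {f: [] for f in fields}}
    if dts is None:
        hs = []
        for n in levels:
            err = solve_case(case, n, dt=dt, t_end=t_end)
            hs.append(1.0 / n)
            for f in fields:
                out["errors"][f].append(err[f])
        out["hs"] = hs
        out["rates"] = {f: fit_rate(hs, out["errors"][f]) for f in fields}
    else:
        # temporal study against a small-dt reference on the same mesh, so
        # the (fixed) spatial error cancels and the implicit-Euler order is
        # measured per field
        n = levels[-1] if hasattr(levels, "__len__") else levels
        dt_ref = min(dts) / 8.0
        _, ref, _ = _solve_final(case, n, dt_ref, t_end)
        for dt_k in dts:
            _, st, _ = _solve_final(case, n, dt_k, t_end)
            # correct the first-order bias of the finite reference:
            # e_meas ~ C (dt - dt_ref) for a first-order scheme
            bias = dt_k / (dt_k - dt_ref)
            for f in fields:
                num = np.linalg.norm(getattr(st, f) - getattr(ref, f))
                den = max(np.linalg.norm(getattr(ref, f)), 1e-300)
                out["errors"][f].append(bias * num / den)
        out["dts"] = list(dts)
        out["rates"] = {f: fit_rate(dts, out["errors"][f]) for f in fields}
        monotone = {
            f: all(np.diff(out["errors"][f]) <= 0) or
               all(np.diff(out["errors"][f]) >= 0)
            for f in fields
        }
        out["monotone"] = monotone
    return out
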