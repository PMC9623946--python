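"""Independent two-compartment lumped compliance oracle.

Used as a brute-force cross-check for the global balance quantities of the
full field model (peak ICP, nadir-to-peak amplitude, spinal/stored volume
partition).  The intracranial pressure p obeys

    dp/dt = Q(t) / (C_b + C_sp(p)),

with a constant parenchymal storage compliance ``C_b = c * V_p`` and the
differential spinal compliance ``C_sp(p) = PVI / (p ln 10)`` of the
exponential pressure-volume law ``p = p0 * 10^(dV/PVI)``.  The model ignores
fluid inertia and viscous losses, which are negligible at these pressures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from icpulse.params import MaterialParams

__all__ = ["LumpedHistory", "solve_lumped", "compliance_partition"]

_LN10 = np.log(10.0)


@dataclass
class LumpedHistory:
    """Time series of the lumped model state."""

    t: np.ndarray
    p: np.ndarray        # ICP [Pa]
    V_sp: np.ndarray     # cumulative volume displaced to the spinal compartment [m^3]
    V_store: np.ndarray  # cumulative volume stored in the parenchyma [m^3]
    params: MaterialParams
    waveform: object
    C_b: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "p": self.p, "V_sp": self.V_sp,
                             "V_store": self.V_store})


def solve_lumped(params: MaterialParams, V_p: float, waveform,
                 n_cycles: int = 1, samples_per_cycle: int = 400,
                 C_sp_const: float | None = None) -> LumpedHistory:
    """Integrate the two-compartment compliance model over n cardiac cycles.

    Parameters
    ----------
    params : MaterialParams
    V_p : float
        Parenchyma volume (m^3); sets C_b = c * V_p.
    waveform : Waveform
        Net blood inflow Q(t) (m^3/s).
    C_sp_const : float, optional
        Replace the differential spinal compliance by a constant (the linear
        limit admits a closed-form solution used in testing).
    """
    if V_p <= 0:
        raise ValueError(f"parenchyma volume must be positive, got {V_p}")
    C_b = params.c * V_p
    p0 = params.p0

    def C_sp(p):
        if C_sp_const is not None:
            return C_sp_const
        return params.PVI / (p * _LN10)

    def rhs(t, y):
        p = y[0]
        if p <= 1e-12:
            raise FloatingPointError(
                "lumped ICP underflow: p -> 0 makes the spinal compliance unbounded"
            )
        csp = C_sp(p)
        dp = waveform(t) / (C_b + csp)
        return [dp, csp * dp, C_b * dp]

    t_end = n_cycles * waveform.T
    t_eval = np.linspace(0.0, t_end, n_cycles * samples_per_cycle + 1)
    sol = solve_ivp(rhs, (0.0, t_end), [p0, 0.0, 0.0], t_eval=t_eval,
                    rtol=1e-8, atol=[1e-8 * p0, 1e-16, 1e-16], method="LSODA",
                    max_step=waveform.T / 50)
    if not sol.success:
        raise RuntimeError(f"lumped oracle integration failed: {sol.message}")
    return LumpedHistory(t=sol.t, p=sol.y[0], V_sp=sol.y[1], V_store=sol.y[2],
                         params=params, waveform=waveform, C_b=C_b)


def compliance_partition(history: LumpedHistory) -> float:
    """Spinal fraction V_sp/(V_sp+V_store) at the end of the net-inflow phase."""
    t_rev = history.waveform.t_rev
    if history.t[-1] < t_rev:
        raise ValueError("history does not cover the net-inflow phase")
    # evaluate on the final recorded cycle
    T = history.waveform.T
    n_full = max(int(np.floor((history.t[-1] + 1e-12) / T)) - 1, 0)
    t_eval = n_full * T + t_rev
    V_sp = np.interp(t_eval, history.t, history.V_sp) - np.interp(
        n_full * T, history.t, history.V_sp)
    V_store = np.interp(t_eval, history.t, history.V_store) - np.interp(
        n_full * T, history.t, history.V_store)
    denom = V_sp + V_store
    if denom == 0:
        raise ZeroDivisionError("no volume was added during the net-inflow phase")
    return float(V_sp / denom)
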