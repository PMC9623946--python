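"""Prescribed periodic net blood inflow Q(t) and the derived source density.

The net blood inflow (arterial inflow minus venous outflow) integrates to
exactly zero over one cardiac cycle: the positive systolic lobe adds a
volume ``V_in`` which the shallower diastolic lobe removes again.  The
synthetic waveform is built from a handful of physiological constraints (period,
reversal time, lobe volume, peak value and peak time); the lobe shape is a
C^1 bump family with a tunable area exponent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = [
    "Waveform",
    "synthetic_net_inflow",
    "from_samples",
    "source_density",
    "default_waveform",
    "read_csv",
    "write_csv",
]


@dataclass(frozen=True)
class Waveform:
    """Periodic net blood inflow rate.

    Attributes
    ----------
    T : float
        Cardiac period (s).
    t_rev : float
        End of the positive (net inflow) lobe within the cycle (s).
    V_in : float
        Volume of the positive lobe (m^3).
    """

    T: float
    t_rev: float
    V_in: float
    _eval: object = None

    def __call__(self, t):
        """Net inflow rate Q(t) in m^3/s (periodic extension)."""
        t = np.mod(np.asarray(t, dtype=float), self.T)
        return self._eval(t)

    def cycle_integral(self, n: int = 4001) -> float:
        """High-order quadrature of Q over one cycle (should be ~0)."""
        val, _ = quad(lambda s: float(self(s)), 0.0, self.T, limit=400)
        return val

    def positive_volume(self) -> float:
        """Quadrature of max(Q, 0) over one cycle."""
        val, _ = quad(lambda s: max(float(self(s)), 0.0), 0.0, self.T,
                      points=[self.t_rev], limit=400)
        return val


def _smoothstep(s):
    return s * s * (3.0 - 2.0 * s)


def _rise_area(a: float) -> float:
    """Integral over [0,1] of smoothstep(s)**a."""
    return quad(lambda s: _smoothstep(s) ** a, 0.0, 1.0)[0]


def _fall_area(a: float) -> float:
    """Integral over [0,1] of (1-smoothstep(s))**a."""
    return quad(lambda s: (1.0 - _smoothstep(s)) ** a, 0.0, 1.0)[0]


def synthetic_net_inflow(T: float = 1.0, t_rev: float = 0.38,
                         V_in: float = 1.54e-6, Q_peak: float = 9.0e-6,
                         t_peak: float = 0.10) -> Waveform:
    """Synthesize a C^1 periodic net inflow from its defining constraints.

    A single positive lobe rises quickly to ``Q_peak`` at ``t_peak``,
    crosses zero at ``t_rev`` and is followed by a shallower negative lobe
    over ``(t_rev, T)`` whose volume exactly cancels ``V_in``.
    """
    if V_in == 0.0 and Q_peak == 0.0:
        return Waveform(T, t_rev, 0.0, _eval=lambda t: np.zeros_like(t))
    if not (0.0 < t_peak < t_rev < T):
        raise ValueError(f"need 0 < t_peak={t_peak} < t_rev={t_rev} < T={T}")
    if V_in <= 0 or Q_peak <= 0:
        raise ValueError("V_in and Q_peak must be positive")
    if V_in >= Q_peak * t_rev:
        raise ValueError(
            f"infeasible lobe: V_in={V_in} cannot exceed Q_peak*t_rev="
            f"{Q_peak * t_rev} for a single-peaked nonnegative lobe"
        )

    # one exponent shapes both lobe halves; solve for the requested volume
    def lobe_volume(a):
        return Q_peak * (t_peak * _rise_area(a) + (t_rev - t_peak) * _fall_area(a))

    lo, hi = 1e-3, 1.0
    while lobe_volume(hi) > V_in:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("infeasible lobe: volume too small for this peak")
    while lobe_volume(lo) < V_in:
        lo /= 2.0
        if lo < 1e-8:
            raise ValueError("infeasible lobe: volume too large for this peak")
    a = brentq(lambda x: lobe_volume(x) - V_in, lo, hi, xtol=1e-14, rtol=1e-14)

    # exact positive-lobe volume by quadrature; the sin^2 negative lobe then
    # cancels it analytically (area of sin^2 bump = 1/2 of its support)
    V_pos = lobe_volume(a)
    A_neg = 2.0 * V_pos / (T - t_rev)

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rise = t < t_peak
        s = np.clip(t[rise] / t_peak, 0.0, 1.0)
        out[rise] = Q_peak * _smoothstep(s) ** a
        fall = (~rise) & (t < t_rev)
        s = (t[fall] - t_peak) / (t_rev - t_peak)
        out[fall] = Q_peak * (1.0 - _smoothstep(s)) ** a
        neg = t >= t_rev
        s = (t[neg] - t_rev) / (T - t_rev)
        out[neg] = -A_neg * np.sin(np.pi * s) ** 2
        return out

    return Waveform(T, t_rev, V_pos, _eval=evaluate)


def from_samples(times, rates, T: float) -> Waveform:
    """Periodic interpolant of sampled net inflow, shifted to zero cycle mean.

    The constant shift mirrors the adjustment of the venous curve used to
    equalize total inflow and outflow over the cycle.
    """
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if times.size == 0:
        raise ValueError("empty sample input")
    if times.size < 4:
        raise ValueError("need at least 4 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if times[0] < 0 or times[-1] >= T:
        raise ValueError("sample times must lie in [0, T)")
    tt = np.concatenate([times, [times[0] + T]])
    rr = np.concatenate([rates, [rates[0]]])
    spline = CubicSpline(tt, rr, bc_type="periodic")
    mean = spline.integrate(tt[0], tt[0] + T) / T

    def evaluate(t):
        t = np.asarray(t, dtype=float)
        tw = np.mod(t - tt[0], T) + tt[0]
        return spline(tw) - mean

    # recompute metadata from the shifted interpolant
    tg = np.linspace(0.0, T, 4096, endpoint=False)
    q = evaluate(tg)
    pos = q > 0
    V_in = float(np.trapezoid(np.maximum(q, 0.0), tg))
    if pos.any() and not pos.all():
        # last time the sign switches from positive to nonpositive
        switch = np.nonzero(pos[:-1] & ~pos[1:])[0]
        t_rev = float(tg[switch[0] + 1]) if len(switch) else T
    else:
        t_rev = T
    return Waveform(T, t_rev, V_in, _eval=evaluate)


def source_density(w: Waveform, V_p: float):
    """Uniform volumetric source density g(t) = Q(t)/V_p (1/s).

    ``V_p`` is the parenchyma volume, so the source integrates to Q(t).
    """
    if V_p <= 0:
        raise ValueError(f"parenchyma volume must be positive, got {V_p}")
    return lambda t: w(t) / V_p


def default_waveform() -> Waveform:
    """The default synthetic waveform used by the standard scenario.

    Period 1 s; positive lobe ends at 38% of the cycle with volume 1.54 ml;
    peak 9 ml/s (spinal peak outflow of 6 ml/s is about two thirds of the
    net-inflow amplitude) at 10% of the cycle.
    """
    return synthetic_net_inflow(T=1.0, t_rev=0.38, V_in=1.54e-6,
                                Q_peak=9.0e-6, t_peak=0.10)


def write_csv(w: Waveform, path, n: int = 200) -> None:
    """Write the waveform as a two-column CSV (t [s], Q [ml/s])."""
    t = np.linspace(0.0, w.T, n, endpoint=False)
    q = w(t) * 1e6
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["t_s", "Q_ml_per_s"])
        for ti, qi in zip(t, q):
            wr.writerow([f"{ti:.6f}", f"{qi:.9g}"])


def read_csv(path, T: float | None = None) -> Waveform:
    """Read a two-column CSV (header required: t [s], Q [ml/s])."""
    rows = []
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if len(header) < 2:
            raise ValueError("waveform CSV needs two columns (t, Q) and a header")
        for row in rd:
            if row:
                rows.append((float(row[0]), float(row[1])))
    if not rows:
        raise ValueError("empty waveform CSV")
    times = np.array([r[0] for r in rows])
    rates = np.array([r[1] for r in rows]) * 1e-6
    if T is None:
        T = times[-1] + (times[-1] - times[0]) / max(len(times) - 1, 1)
    return from_samples(times, rates, T)
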