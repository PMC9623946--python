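"""Clinically motivated quantities of interest from a state history.

All cycle-scoped scalars are computed on the final simulated cycle.  ICP is
identified with the fluid pressure in the CSF spaces and with the total
pressure in the parenchyma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from icpulse.fem import assemble as asm
from icpulse.fem.assemble import FacetContext
from icpulse.params import MMHG_TO_PA
from icpulse.timeloop import StateHistory

__all__ = [
    "QoITable",
    "probe_pressure",
    "pressure_amplitude",
    "flux_across",
    "stroke_volume",
    "transmantle_gradient",
    "peak_displacement",
    "compliance_partition_fem",
    "compute_qoi",
]


def probe_pressure(history: StateHistory, point) -> np.ndarray:
    """ICP series at a named probe or an arbitrary point.

    Returns p_f at CSF points and the total pressure phi at parenchyma
    points, per time level.
    """
    if isinstance(point, str):
        return history.probe_series[point].copy()
    dom = history.cfg.domain
    op = history.op
    pt = np.asarray(point, dtype=float)
    cid, ref = dom.mesh.locate_points(pt)
    if cid[0] < 0:
        raise ValueError(f"point {point} lies outside the mesh")
    from icpulse.geometry import CellTag

    if dom.mesh.cell_tags[cid[0]] == CellTag.CSF:
        space, fld = op.spaces["p_f"], "p_f"
    else:
        space, fld = op.spaces["phi"], "phi"
    if not history.states:
        raise ValueError("field states were not stored for this run")
    pos = np.nonzero(space.cells == cid[0])[0][0]
    dofs = space.cell_dofs[pos]
    wts = space.tabulate(ref)[0]
    return np.array([wts @ getattr(st, fld)[dofs] for st in history.states])


def pressure_amplitude(series: np.ndarray, cycle_idx=None) -> float:
    """Nadir-to-peak (max - min) amplitude over the final cycle."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty pressure series")
    if cycle_idx is not None:
        series = series[cycle_idx]
    return float(series.max() - series.min())


def flux_across(history: StateHistory, surface: str) -> np.ndarray:
    """Flux series across a named surface with its stored orientation.

    Spinal outlet: cranium -> spine positive; aqueduct: ventricle -> SAS
    positive.
    """
    if surface in history.flux_series:
        return history.flux_series[surface].copy()
    dom = history.cfg.domain
    if surface not in dom.named_surfaces:
        raise KeyError(f"unknown surface {surface!r}")
    fids, oc = dom.named_surfaces[surface]
    ctx = FacetContext(dom.mesh, fids, oc)
    if not history.states:
        raise ValueError("field states were not stored for this run")
    return np.array([asm.facet_flux(ctx, history.op.spaces["u"], st.u)
                     for st in history.states])


def stroke_volume(flux_series: np.ndarray, dt: float, rule: str = "rectangle") -> float:
    """Maximum of the cumulative flow volume over the (final) cycle.

    The default right-rectangle rule matches the implicit-Euler bookkeeping
    of the time loop exactly; a trapezoidal variant is available.
    """
    q = np.asarray(flux_series, dtype=float)
    if q.size == 0:
        raise ValueError("empty flux series")
    if rule == "rectangle":
        cum = np.concatenate([[0.0], np.cumsum(q[1:]) * dt])
    elif rule == "trapezoid":
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (q[1:] + q[:-1])) * dt])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return float(cum.max())


def transmantle_gradient(p_lv: np.ndarray, p_sas: np.ndarray,
                         distance: float) -> np.ndarray:
    """(p_lv - p_sas)/distance per time point [Pa/m]."""
    p_lv = np.asarray(p_lv)
    p_sas = np.asarray(p_sas)
    if p_lv.shape != p_sas.shape:
        raise ValueError("probe series are not time-aligned")
    if distance <= 0:
        raise ValueError("probe distance must be positive")
    return (p_lv - p_sas) / distance


def peak_displacement(history: StateHistory) -> tuple[float, float]:
    """(max |d| over the final cycle, time of occurrence)."""
    idx = history.final_cycle
    md = history.max_disp[idx]
    k = int(np.argmax(md))
    return float(md[k]), float(history.times[idx][k])


def compliance_partition_fem(history: StateHistory) -> float:
    """Spinal fraction of the added volume at the end of the net-inflow phase.

    Evaluated on the final cycle: cumulative spinal outflow divided by
    cumulative source volume, both measured from the cycle start to t_rev.
    """
    cfg = history.cfg
    idx = history.final_cycle
    t0 = history.times[idx[0]]
    t_rev = t0 + cfg.waveform.t_rev
    k = idx[np.searchsorted(history.times[idx], t_rev - 1e-12)]
    dV = history.dV_out[k] - history.dV_out[idx[0]]
    Va = history.V_added[k] - history.V_added[idx[0]]
    if Va == 0:
        raise ZeroDivisionError("no source volume was added over the inflow phase")
    return float(dV / Va)


@dataclass
class QoITable:
    """Scalars and series of the quantities of interest (SI units)."""

    peak_icp: float
    lv_pressure_amplitude: float
    spinal_stroke_volume: float
    peak_aqueduct_flow: float
    aqueduct_stroke_volume: float
    peak_displacement: float
    peak_displacement_time: float
    peak_transmantle_gradient: float         # max |.|
    peak_transmantle_gradient_signed: float  # max signed value
    probe_distance: float
    compliance_partition: float
    displaced_volume: float                  # spinal volume at t_rev [m^3]
    stored_volume: float                     # source minus displaced [m^3]
    series: dict = field(default_factory=dict)

    def scalars(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "series"}
        return d

    def clinical(self) -> dict:
        """Scalars converted to the units used in clinical reporting."""
        return {
            "peak_icp_mmHg": self.peak_icp / MMHG_TO_PA,
            "lv_pressure_amplitude_mmHg": self.lv_pressure_amplitude / MMHG_TO_PA,
            "spinal_stroke_volume_ml": self.spinal_stroke_volume * 1e6,
            "peak_aqueduct_flow_ml_per_s": self.peak_aqueduct_flow * 1e6,
            "aqueduct_stroke_volume_ml": self.aqueduct_stroke_volume * 1e6,
            "peak_displacement_mm": self.peak_displacement * 1e3,
            "peak_displacement_time_s": self.peak_displacement_time,
            "peak_transmantle_gradient_mmHg_per_m":
                self.peak_transmantle_gradient / MMHG_TO_PA,
            "probe_distance_m": self.probe_distance,
            "compliance_partition_percent": 100.0 * self.compliance_partition,
            "displaced_volume_ml": self.displaced_volume * 1e6,
            "stored_volume_ml": self.stored_volume * 1e6,
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(sorted(self.clinical().items()),
                     columns=["quantity", "value"]).to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.clinical(), indent=2))


def compute_qoi(history: StateHistory) -> QoITable:
    """Assemble the full QoI table from a run (final cycle scalars)."""
    cfg = history.cfg
    idx = history.final_cycle
    dt = history.dt
    lv = history.probe_series["LV"]
    sas = history.probe_series.get("SAS")

    spinal = history.flux_series.get("SPINAL_OUTLET",
                                     np.zeros_like(history.times))
    aque = history.flux_series.get("AQUEDUCT", np.zeros_like(history.times))
    sv_spinal = stroke_volume(spinal[idx], dt)
    sv_aq = stroke_volume(aque[idx], dt)

    pd_val, pd_time = peak_displacement(history)
    if sas is not None:
        p_lv = np.asarray(cfg.domain.probes["LV"].point)
        p_sas = np.asarray(cfg.domain.probes["SAS"].point)
        dist = float(np.linalg.norm(p_lv - p_sas))
        grad = transmantle_gradient(lv[idx], sas[idx], dist)
        g_abs = float(np.max(np.abs(grad)))
        g_signed = float(grad[np.argmax(np.abs(grad))])
    else:
        dist, g_abs, g_signed = np.nan, np.nan, np.nan

    part = compliance_partition_fem(history)
    t0 = history.times[idx[0]]
    k = idx[np.searchsorted(history.times[idx], t0 + cfg.waveform.t_rev - 1e-12)]
    displaced = history.dV_out[k] - history.dV_out[idx[0]]
    added = history.V_added[k] - history.V_added[idx[0]]

    series = {
        "t": history.times,
        "p_LV": lv,
        "p_SAS": sas,
        "p_V4": history.probe_series.get("V4"),
        "spinal_flux": spinal,
        "aqueduct_flux": aque,
        "dV_out": history.dV_out,
    }
    return QoITable(
        peak_icp=float(lv[idx].max()),
        lv_pressure_amplitude=pressure_amplitude(lv, idx),
        spinal_stroke_volume=sv_spinal,
        peak_aqueduct_flow=float(np.max(np.abs(aque[idx]))),
        aqueduct_stroke_volume=sv_aq,
        peak_displacement=pd_val,
        peak_displacement_time=pd_time,
        peak_transmantle_gradient=g_abs,
        peak_transmantle_gradient_signed=g_signed,
        probe_distance=dist,
        compliance_partition=part,
        displaced_volume=float(displaced),
        stored_volume=float(added - displaced),
        series=series,
    )
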