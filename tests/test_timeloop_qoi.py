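"""Transient driver and quantities-of-interest tests."""

import numpy as np
import pytest

from icpulse.geometry import FacetTag
from icpulse.params import MMHG_TO_PA, MaterialParams
from icpulse.qoi import (compute_qoi, flux_across, peak_displacement,
                         pressure_amplitude, probe_pressure, stroke_volume,
                         transmantle_gradient)
from icpulse.timeloop import RunConfig, periodic_state_check, run_transient
from icpulse.waveform import synthetic_net_inflow


@pytest.fixture(scope="module")
def zero_run(ideal_domain):
    w = synthetic_net_inflow(V_in=0.0, Q_peak=0.0)
    cfg = RunConfig(domain=ideal_domain, params=MaterialParams(), waveform=w,
                    n_cycles=2, steps_per_cycle=10, store_fields=True)
    return run_transient(cfg)


class TestRunTransient:
    def test_zero_waveform_stays_at_rest(self, zero_run):
        p0 = MaterialParams().p0
        assert np.abs(zero_run.dV_out).max() == pytest.approx(0.0, abs=1e-12)
        assert np.abs(zero_run.probe_series["LV"] - p0).max() < 1e-6 * p0
        assert zero_run.max_disp.max() < 1e-9

    def test_peak_icp(self, standard_run):
        idx = standard_run.final_cycle
        peak = standard_run.probe_series["LV"][idx].max() / MMHG_TO_PA
        assert peak == pytest.approx(8.4, rel=0.1)

    def test_volume_bookkeeping_every_step(self, standard_run):
        """|V_added - V_stored - dV_out| < 1% of the lobe volume, per step."""
        h = standard_run
        V_in = h.cfg.waveform.V_in
        resid = np.abs(h.V_added - h.V_stored - h.dV_out)
        assert resid.max() < 0.01 * V_in
        # the discrete identity is in fact solver-exact
        assert resid.max() < 1e-8 * V_in

    def test_config_validation(self, ideal_domain, waveform):
        with pytest.raises(ValueError):
            RunConfig(domain=ideal_domain, params=MaterialParams(),
                      waveform=waveform, n_cycles=0)
        with pytest.raises(ValueError):
            RunConfig(domain=ideal_domain, params=MaterialParams(),
                      waveform=waveform, steps_per_cycle=4)


class TestPeriodicStateCheck:
    def test_zero_waveform(self, zero_run):
        assert periodic_state_check(zero_run) == 0.0

    def test_standard_below_threshold(self, standard_run):
        assert periodic_state_check(standard_run) < 0.05

    def test_decreasing_across_cycle_pairs(self, standard_run):
        h = standard_run
        trace = h.probe_series["LV"]
        diffs = []
        for c in range(h.cfg.n_cycles - 1):
            a = trace[h.cycle_indices(c)]
            b = trace[h.cycle_indices(c + 1)]
            diffs.append(np.linalg.norm(b - a))
        assert all(np.diff(diffs) < 0)

    def test_requires_two_cycles(self, ideal_domain, waveform):
        cfg = RunConfig(domain=ideal_domain, params=MaterialParams(),
                        waveform=synthetic_net_inflow(V_in=0.0, Q_peak=0.0),
                        n_cycles=1, steps_per_cycle=10)
        h = run_transient(cfg)
        with pytest.raises(ValueError):
            periodic_state_check(h)


class TestProbePressure:
    def test_rest_history_constant(self, zero_run):
        p0 = MaterialParams().p0
        for name in ("LV", "SAS", "V4"):
            s = probe_pressure(zero_run, name)
            assert np.allclose(s, p0, rtol=1e-6)

    def test_arbitrary_point_in_parenchyma(self, zero_run):
        # total pressure at rest is alpha*p0 in the parenchyma
        p = MaterialParams()
        dom = zero_run.cfg.domain
        cent = dom.mesh.cell_centroids()[dom.parenchyma_cells[0]]
        s = probe_pressure(zero_run, cent)
        assert np.allclose(s, p.alpha * p.p0, rtol=1e-6)

    def test_outside_point(self, zero_run):
        with pytest.raises(ValueError):
            probe_pressure(zero_run, np.array([1.0, 1.0, 1.0]))


class TestPressureAmplitude:
    def test_constant(self):
        assert pressure_amplitude(np.full(10, 3.0)) == 0.0

    def test_sinusoid(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        assert pressure_amplitude(2.5 * np.sin(t)) == pytest.approx(5.0,
                                                                    rel=1e-4)

    def test_empty(self):
        with pytest.raises(ValueError):
            pressure_amplitude(np.array([]))


class TestFluxAcross:
    def test_unknown_surface(self, standard_run):
        with pytest.raises(KeyError):
            flux_across(standard_run, "NOPE")

    def test_recomputed_matches_recorded(self, standard_run):
        rec = standard_run.flux_series.pop("SPINAL_OUTLET")
        try:
            re2 = flux_across(standard_run, "SPINAL_OUTLET")
        finally:
            standard_run.flux_series["SPINAL_OUTLET"] = rec
        assert np.allclose(re2, rec, rtol=1e-12, atol=1e-18)

    def test_spinal_peak_scale(self, standard_run):
        q = standard_run.flux_series["SPINAL_OUTLET"][standard_run.final_cycle]
        assert q.max() * 1e6 == pytest.approx(6.0, rel=0.15)


class TestStrokeVolume:
    def test_zero(self):
        assert stroke_volume(np.zeros(11), 0.1) == 0.0

    def test_sinusoid_analytic(self):
        # Q0*sin(2*pi*t/T): max cumulative volume = Q0*T/pi
        T, Q0, n = 1.0, 2.0, 4000
        t = np.linspace(0, T, n + 1)
        q = Q0 * np.sin(2 * np.pi * t / T)
        sv = stroke_volume(q, T / n, rule="trapezoid")
        assert sv == pytest.approx(Q0 * T / np.pi, rel=1e-5)

    def test_empty(self):
        with pytest.raises(ValueError):
            stroke_volume(np.array([]), 0.1)

    def test_rectangle_matches_dV_out_trace(self, standard_run):
        """Same quadrature as the time loop: identical to the dV_out trace."""
        h = standard_run
        idx = h.final_cycle
        sv = stroke_volume(h.flux_series["SPINAL_OUTLET"][idx], h.dt)
        dv = h.dV_out[idx] - h.dV_out[idx[0]]
        assert sv == pytest.approx(dv.max(), rel=1e-10)

    def test_sign_convention_mirror(self):
        rng = np.random.default_rng(3)
        q = rng.standard_normal(101)
        # reversing orientation and the cycle direction preserves the
        # stroke volume of the mirrored cycle
        sv1 = stroke_volume(q, 0.01)
        sv2 = stroke_volume(-q[::-1], 0.01)
        cum1 = np.concatenate([[0], np.cumsum(q[1:])]) * 0.01
        assert sv1 == pytest.approx(cum1.max())
        assert sv2 >= 0 or sv2 == pytest.approx(0.0)


class TestTransmantleGradient:
    def test_identical_series(self):
        s = np.linspace(0, 1, 10)
        assert np.all(transmantle_gradient(s, s, 0.06) == 0.0)

    def test_arithmetic(self):
        lv = np.array([0.0108 * MMHG_TO_PA])
        sas = np.array([0.0])
        g = transmantle_gradient(lv, sas, 0.06)
        assert g[0] / MMHG_TO_PA == pytest.approx(0.18, rel=1e-10)

    def test_distance_linearity(self):
        lv = np.array([2.0, 1.0])
        sas = np.array([0.5, 0.5])
        g1 = transmantle_gradient(lv, sas, 0.06)
        g2 = transmantle_gradient(lv, sas, 0.03)
        assert np.allclose(g2, 2 * g1)

    def test_mismatched_grids(self):
        with pytest.raises(ValueError):
            transmantle_gradient(np.zeros(5), np.zeros(6), 0.06)


class TestPeakDisplacement:
    def test_rest(self, zero_run):
        val, t = peak_displacement(zero_run)
        assert val < 1e-9

    def test_standard_nonzero(self, standard_run):
        val, t = peak_displacement(standard_run)
        assert val > 1e-6  # micrometers at least
        idx = standard_run.final_cycle
        assert standard_run.times[idx[0]] <= t <= standard_run.times[idx[-1]]


class TestQoITable:
    def test_all_six_quantities_present(self, standard_run):
        q = compute_qoi(standard_run)
        c = q.clinical()
        for key in ("peak_aqueduct_flow_ml_per_s", "aqueduct_stroke_volume_ml",
                    "peak_displacement_mm",
                    "peak_transmantle_gradient_mmHg_per_m",
                    "lv_pressure_amplitude_mmHg", "spinal_stroke_volume_ml"):
            assert key in c and np.isfinite(c[key])

    def test_scalar_invariants(self, standard_run):
        q = compute_qoi(standard_run)
        assert q.spinal_stroke_volume >= 0
        assert q.aqueduct_stroke_volume >= 0
        assert q.lv_pressure_amplitude >= 0

    def test_serialization(self, standard_run, tmp_path):
        q = compute_qoi(standard_run)
        q.to_csv(tmp_path / "q.csv")
        q.to_json(tmp_path / "q.json")
        import json

        data = json.loads((tmp_path / "q.json").read_text())
        assert data["spinal_stroke_volume_ml"] == pytest.approx(
            q.spinal_stroke_volume * 1e6)
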