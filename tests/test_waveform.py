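import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icpulse.waveform import (default_waveform, from_samples, read_csv,
                              source_density, synthetic_net_inflow, write_csv)


class TestSyntheticNetInflow:
    def test_positive_lobe_volume(self):
        w = default_waveform()
        assert w.V_in == pytest.approx(1.54e-6, rel=1e-10)
        assert w.positive_volume() == pytest.approx(1.54e-6, rel=1e-6)

    def test_zero_cycle_mean(self):
        w = default_waveform()
        # positive lobe quadrature cancels the analytic negative-lobe area
        from scipy.integrate import quad
        pos = quad(lambda s: float(w(s)), 0.0, w.t_rev, points=[0.1],
                   limit=200, epsabs=1e-14)[0]
        neg = quad(lambda s: float(w(s)), w.t_rev, w.T, limit=200,
                   epsabs=1e-14)[0]
        assert abs(pos + neg) < 1e-10 * w.V_in

    def test_peak(self):
        w = default_waveform()
        t = np.linspace(0, 1, 5001)
        assert w(t).max() == pytest.approx(9.0e-6, rel=1e-12)
        assert float(w(0.10)) == pytest.approx(9.0e-6, rel=1e-12)

    def test_reversal_time(self):
        w = default_waveform()
        assert float(w(w.t_rev)) == pytest.approx(0.0, abs=1e-18)
        assert float(w(w.t_rev - 1e-3)) > 0
        assert float(w(w.t_rev + 1e-3)) < 0

    def test_zero_waveform(self):
        w = synthetic_net_inflow(V_in=0.0, Q_peak=0.0)
        assert np.all(w(np.linspace(0, 2, 50)) == 0.0)

    def test_periodicity(self):
        w = default_waveform()
        t = np.linspace(0, 1, 101)
        assert np.allclose(w(t), w(t + w.T), atol=0)
        assert np.allclose(w(t), w(t + 5 * w.T), atol=0)

    def test_continuity(self):
        w = default_waveform()
        t = np.linspace(0, 1, 20001)
        q = w(t)
        assert np.abs(np.diff(q)).max() < 5e-3 * 9e-6  # no jumps

    def test_infeasible(self):
        with pytest.raises(ValueError):
            synthetic_net_inflow(T=1.0, t_rev=0.38, V_in=5e-6, Q_peak=9e-6)
        with pytest.raises(ValueError):
            synthetic_net_inflow(T=1.0, t_rev=0.05, V_in=1e-6, Q_peak=9e-6,
                                 t_peak=0.1)

    @given(
        t_rev=st.floats(0.2, 0.6), vfrac=st.floats(0.15, 0.85),
        qp=st.floats(1e-6, 2e-5), tp_frac=st.floats(0.15, 0.8),
    )
    @settings(max_examples=20, deadline=None)
    def test_property_volume_and_mean(self, t_rev, vfrac, qp, tp_frac):
        V_in = vfrac * qp * t_rev
        w = synthetic_net_inflow(T=1.0, t_rev=t_rev, V_in=V_in, Q_peak=qp,
                                 t_peak=tp_frac * t_rev)
        assert w.V_in == pytest.approx(V_in, rel=1e-8)
        t = np.linspace(0, 1, 20001)
        mean = np.trapezoid(w(t), t)
        assert abs(mean) < 1e-5 * V_in  # grid-level check


class TestFromSamples:
    def test_sinusoid(self):
        T = 1.0
        t = np.linspace(0, T, 64, endpoint=False)
        w = from_samples(t, 2e-6 * np.sin(2 * np.pi * t), T)
        tt = np.linspace(0, 1, 301)
        assert np.allclose(w(tt), 2e-6 * np.sin(2 * np.pi * tt), atol=1e-9)

    def test_constant_shifted_to_zero(self):
        t = np.linspace(0, 1, 16, endpoint=False)
        w = from_samples(t, np.full(16, 3.3e-6), 1.0)
        assert np.allclose(w(t), 0.0, atol=1e-18)

    def test_mean_removed(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 32, endpoint=False)
        q = 1e-6 * rng.standard_normal(32)
        w = from_samples(t, q, 1.0)
        # output - input is a constant (-mean) at the sample points
        diff = w(t) - q
        assert np.allclose(diff, diff[0], atol=1e-12 * 1e-6)

    @pytest.mark.parametrize("times,rates", [
        ([], []),
        ([0.0, 0.1], [1.0, 2.0]),
        ([0.0, 0.2, 0.2, 0.4], [1, 2, 3, 4]),
    ])
    def test_bad_input(self, times, rates):
        with pytest.raises(ValueError):
            from_samples(times, rates, 1.0)

    def test_csv_round_trip(self, tmp_path):
        w = default_waveform()
        path = tmp_path / "wave.csv"
        write_csv(w, path, n=400)
        w2 = read_csv(path, T=1.0)
        t = np.linspace(0.02, 0.95, 37)
        assert np.allclose(w2(t), w(t), atol=2e-8)


class TestSourceDensity:
    def test_peak_density(self):
        g = source_density(default_waveform(), 1.36954e-3)
        assert float(g(0.10)) == pytest.approx(9e-6 / 1.36954e-3, rel=1e-12)

    def test_zero(self):
        g = source_density(synthetic_net_inflow(V_in=0.0, Q_peak=0.0), 1.0)
        assert float(g(0.3)) == 0.0

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            source_density(default_waveform(), 0.0)

    def test_integral_over_mesh(self, ideal_domain):
        # the uniform density integrates back to Q(t) on the actual mesh
        w = default_waveform()
        vols = ideal_domain.mesh.cell_volumes()
        V_p = vols[ideal_domain.parenchyma_cells].sum()
        g = source_density(w, V_p)
        for t in (0.1, 0.25, 0.7):
            assert float(g(t)) * V_p == pytest.approx(float(w(t)), rel=1e-12)
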