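"""Ionic current formalism, gate updates, firing classification, and the
low-threshold-calcium rebound property of thalamic relay cells."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcnet.channels import (ChannelSpec, GatingKinetics, cell_template,
                            classify_firing, gate_step, ionic_current)
from tcnet.engine import detect_spikes, run_current_protocol
from tcnet.fixtures import make_spike_train, make_spike_voltage
from tcnet.kinetics import GATE_REGISTRY


class TestIonicCurrent:
    def test_direct_evaluation(self):
        ch = ChannelSpec("Naf", 0.01, -90.0, N=3, M=1)
        # 0.01 * 0.5^3 * 1 * (-60 + 90) = 0.0375
        assert ionic_current(ch, -60.0, m=0.5, h=1.0) == pytest.approx(0.0375)

    def test_zero_at_reversal_and_zero_conductance(self):
        ch = ChannelSpec("K", 0.5, -95.0, N=4)
        assert ionic_current(ch, -95.0, m=0.3) == 0.0
        ch0 = ChannelSpec("K", 0.0, -95.0, N=4)
        for v in (-120.0, -60.0, 40.0):
            assert ionic_current(ch0, v, m=0.7) == 0.0

    def test_linear_in_gmax_and_driving_force(self):
        a = ChannelSpec("x", 1.0, -70.0, N=1)
        b = ChannelSpec("x", 3.0, -70.0, N=1)
        i1 = ionic_current(a, -50.0, m=0.4)
        assert ionic_current(b, -50.0, m=0.4) == pytest.approx(3 * i1)
        assert ionic_current(a, -30.0, m=0.4) == pytest.approx(2 * i1)

    def test_invalid_gate_rejected(self):
        ch = ChannelSpec("x", 1.0, -70.0, N=1)
        with pytest.raises(ValueError):
            ionic_current(ch, -50.0, m=1.5)


class TestGateStep:
    def _kin(self, x_inf=1.0, tau=10.0):
        return GatingKinetics(lambda V: x_inf, lambda V: tau)

    def test_fixed_point_unchanged(self):
        kin = self._kin(0.42, 5.0)
        assert gate_step(kin, 0.42, -60.0, 1.0) == pytest.approx(0.42)

    def test_closed_form_relaxation(self):
        # x0=0, x_inf=1, tau=10, dt=10 -> 1 - e^-1
        kin = self._kin(1.0, 10.0)
        assert gate_step(kin, 0.0, -60.0, 10.0) == pytest.approx(1 - math.exp(-1))

    def test_small_dt_limit(self):
        kin = self._kin(1.0, 10.0)
        assert gate_step(kin, 0.5, -60.0, 1e-9) == pytest.approx(0.5, abs=1e-8)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            gate_step(self._kin(), 0.5, -60.0, 0.0)

    def test_agrees_with_fine_explicit_integration(self):
        """Exact-exponential update vs explicit Euler oracle at dt=0.025."""
        x_inf, tau = GATE_REGISTRY[("TC", "CaT", "h")]
        for V in (-90.0, -70.0, -50.0):
            x = 0.2
            exact = gate_step(GatingKinetics(x_inf, tau), x, V, 0.025)
            fine = x
            sub = 0.025 / 2000
            xi, tv = float(x_inf(V)), float(tau(V))
            for _ in range(2000):
                fine += sub * (xi - fine) / tv
            assert abs(exact - fine) < 1e-6

    @given(V=st.floats(-120, 60), x0=st.floats(0, 1),
           steps=st.integers(1, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gates_stay_bounded_under_iteration(self, V, x0, steps):
        x_inf, tau = GATE_REGISTRY[("cortical", "Naf", "m")]
        kin = GatingKinetics(x_inf, tau)
        x = x0
        for _ in range(steps):
            x = gate_step(kin, x, V, 0.5)
            assert 0.0 <= x <= 1.0


class TestKineticsRegistry:
    @pytest.mark.parametrize("key", sorted(GATE_REGISTRY), ids="-".join)
    def test_steady_state_and_tau_well_behaved(self, key):
        x_inf, tau = GATE_REGISTRY[key]
        V = np.linspace(-120, 60, 361)
        xi, tv = np.asarray(x_inf(V), float), np.asarray(tau(V), float)
        assert np.all((xi >= 0) & (xi <= 1))
        assert np.all(tv > 0)
        assert np.all(np.isfinite(xi)) and np.all(np.isfinite(tv))


class TestCellTemplates:
    def test_channel_inventories_match_membrane_equations(self):
        cortical = {"Leak", "Naf", "Nap", "Ka", "K2", "Kdr", "Km", "Kc",
                    "Kahp", "CaT", "CaL", "h"}
        for cls in ("RS", "IB", "NRS", "LTS"):
            names = {ch.name for ch in cell_template(cls).channels}
            assert names == cortical
        tc = {ch.name for ch in cell_template("TC").channels}
        assert tc == {"Leak", "KLeak", "Naf", "K", "CaT", "h"}
        re = {ch.name for ch in cell_template("RE").channels}
        assert re == {"Leak", "Naf", "K", "CaT"}

    def test_capacitance_by_class(self):
        for cls in ("RS", "IB", "NRS"):
            assert cell_template(cls).Cm == 0.9
        for cls in ("LTS", "TC", "RE"):
            assert cell_template(cls).Cm == 1.0


class TestClassifyFiring:
    def test_silent_trace(self):
        v = np.full(20000, -65.0)
        assert classify_firing(v, 0.1) == "silent"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_firing(np.array([]), 0.1)

    def test_regular_train(self):
        times = make_spike_train("regular", 2000.0, interval=100.0)
        v = make_spike_voltage(times, 2000.0)
        assert classify_firing(v, 0.1) == "regular_spiking"

    def test_burst_train(self):
        times = make_spike_train("burst", 2000.0, n_per_burst=3, intra=5.0,
                                 inter=300.0)
        v = make_spike_voltage(times, 2000.0)
        assert classify_firing(v, 0.1) == "bursting"


class TestThalamicRebound:
    def test_tc_rebound_requires_low_threshold_calcium(self):
        """A TC cell released from a 500 ms hyperpolarizing step fires a
        rebound burst within 200 ms; deleting the low-threshold Ca current
        abolishes it."""
        steps = [(1000.0, 0.0), (500.0, -0.3), (250.0, 0.0)]
        _, v = run_current_protocol("TC", steps)
        release = slice(15000, 17000)  # 200 ms after release at 10 kHz
        spikes = detect_spikes(v[release], 0.1)
        assert len(spikes) >= 1

        cell = cell_template("TC").without_channel("CaT")
        _, v0 = run_current_protocol("TC", steps, cell=cell)
        assert len(detect_spikes(v0[release], 0.1)) == 0
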