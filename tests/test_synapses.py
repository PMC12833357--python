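"""Two-state kinetic synapse model: closed form, modifiers, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcnet import tables
from tcnet.fixtures import synapse_oracle
from tcnet.synapses import (ALLO_FACTORS, SynapseSpec, apply_allo,
                            apply_mutation, s_profile, synaptic_current)


def _spec(**kw):
    base = dict(receptor="GABA_A", gbar=0.09, alpha=0.1, beta=0.2)
    base.update(kw)
    return SynapseSpec(**base)


class TestSteadyStateAndTau:
    def test_re_to_tc_rates(self):
        # alpha*C_max = 20 * 0.5 = 10 /ms with beta = 0.162 /ms
        spec = _spec(alpha=20.0, beta=0.162)
        assert spec.s_inf == pytest.approx(10.0 / 10.162, rel=1e-6)
        assert spec.tau_s == pytest.approx(1.0 / 10.162, rel=1e-6)

    def test_s_inf_bounded(self):
        for alpha, beta in [(0.01, 5.0), (50.0, 0.001)]:
            spec = _spec(alpha=alpha, beta=beta)
            assert 0.0 < spec.s_inf < 1.0
            assert spec.tau_s > 0.0


class TestSProfile:
    def test_boundary_is_s0(self):
        spec = _spec()
        for s0 in (0.0, 0.3, 1.0):
            assert s_profile(spec, s0, 0.0) == pytest.approx(s0)

    def test_long_time_decays_to_zero(self):
        spec = _spec()
        assert s_profile(spec, 0.5, 5000.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            s_profile(_spec(), 0.0, -1.0)

    def test_matches_brute_force_ode(self):
        """Closed-form pulse solution vs fine-step explicit integration."""
        for spec in (
            _spec(alpha=0.1, beta=0.2),
            _spec(alpha=20.0, beta=0.162),
            _spec(receptor="AMPA", gbar=1.0, alpha=1.0, beta=0.15),
        ):
            t = np.arange(0, 20.0, 0.01)
            closed = s_profile(spec, 0.0, t)
            oracle = synapse_oracle(spec, [0.0], 20.0, dt=0.0005)
            oracle_at = oracle[np.round(t / 0.0005).astype(int)]
            assert np.max(np.abs(closed - oracle_at)) < 1e-6

    @given(s0=st.floats(0, 1), t=st.floats(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_result_always_in_unit_interval(self, s0, t):
        spec = _spec(alpha=2.0, beta=0.05)
        assert 0.0 <= s_profile(spec, s0, t) <= 1.0


class TestSynapticCurrent:
    def test_zero_when_closed_or_at_reversal(self):
        spec = _spec()
        assert synaptic_current(spec, 0.0, -60.0) == 0.0
        assert synaptic_current(spec, 0.7, spec.E_syn) == 0.0

    def test_re_to_re_weighted_current(self):
        # gbar 0.2 uS shared over 11 inputs, half-open, 20 mV driving force
        spec = SynapseSpec("GABA_A", 0.2, 20.0, 0.162)
        i = synaptic_current(spec, 0.5, -60.0, n_in=11)
        assert i == pytest.approx((0.2 / 11) * 0.5 * 20.0, rel=1e-9)


class TestAllo:
    def test_lts_to_rs_transform(self):
        spec = _spec(alpha=0.1, beta=0.2, gbar=0.09, C_dur=0.3)
        post = apply_allo(spec)
        assert post.alpha == pytest.approx(0.158)
        assert post.beta == pytest.approx(0.148)
        assert post.gbar == pytest.approx(0.0999)
        assert post.C_dur == pytest.approx(0.342)
        assert post.variant == "post-ALLO"

    def test_factor_ratios_and_decay_lengthening(self):
        spec = _spec(alpha=0.625, beta=0.109)
        post = apply_allo(spec)
        assert post.alpha / spec.alpha == pytest.approx(1.58)
        assert (1 / post.beta) / (1 / spec.beta) == pytest.approx(1 / 0.74)

    def test_double_application_and_wrong_receptor_rejected(self):
        post = apply_allo(_spec())
        with pytest.raises(ValueError):
            apply_allo(post)
        with pytest.raises(ValueError):
            apply_allo(SynapseSpec("AMPA", 1.0, 0.1, 0.15))

    @pytest.mark.parametrize(
        "row", list(tables.synapse_table().query("receptor == 'GABA_A'")
                    .itertuples(index=False)), ids=lambda r: f"{r.pre}->{r.post}")
    def test_allo_increases_integrated_conductance(self, row):
        """Post-ALLO synapses deliver more charge (integral of g*s over
        500 ms after one spike) than Control, for every GABA_A projection."""
        spec = SynapseSpec(row.receptor, row.gbar, row.alpha, row.beta,
                           pre_class=row.pre, post_class=row.post)
        post = apply_allo(spec)
        t = np.arange(0, 500.0, 0.005)
        q_control = spec.gbar * np.trapezoid(s_profile(spec, 0.0, t), t)
        q_post = post.gbar * np.trapezoid(s_profile(post, 0.0, t), t)
        assert q_post > q_control
        # peak open fraction is non-decreasing too
        assert s_profile(post, 0.0, post.C_dur) >= \
            s_profile(spec, 0.0, spec.C_dur) - 1e-12


class TestMutation:
    def test_scaling_to_ten_percent(self):
        spec = SynapseSpec("GABA_A", 0.75, 0.1, 0.01, post_class="NRS")
        scaled = apply_mutation(spec, 0.10)
        assert scaled.g_effective == pytest.approx(0.075)

    def test_full_fraction_is_identity(self):
        spec = SynapseSpec("GABA_A", 0.75, 0.1, 0.01, post_class="NRS")
        assert apply_mutation(spec, 1.0) == spec

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            apply_mutation(_spec(), 0.0)
        with pytest.raises(ValueError):
            apply_mutation(SynapseSpec("AMPA", 1.0, 0.1, 0.15), 0.5)
        with pytest.raises(ValueError):
            apply_mutation(
                SynapseSpec("GABA_A", 0.02, 20.0, 0.162, post_class="TC"), 0.5)

    def test_commutes_with_allo(self):
        spec = SynapseSpec("GABA_A", 0.75, 0.1, 0.01, post_class="NRS")
        a = apply_allo(apply_mutation(spec, 0.1))
        b = apply_mutation(apply_allo(spec), 0.1)
        assert a == b
        assert a.g_effective == pytest.approx(0.75 * 1.11 * 0.1)
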