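"""Unit and property tests for the neuron/synapse update rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikefix.dynamics import (HomeostasisParams, LIFParams, NeuronState,
                               STDPParams, SynapseState, decay_conductances,
                               decay_traces, effective_threshold,
                               inject_spike, lif_step, normalize_weights,
                               stdp_on_post, stdp_on_pre, synaptic_current,
                               theta_decay, theta_on_spike, trace_to_w)
from spikefix.fixedpoint import FixedSpec


def _syn(spec, w=0.5, a_pre=0.0, a_post=0.0, plastic=True):
    return SynapseState(0, 1, w=spec.to_w_units(w),
                        a_pre=spec.to_trace_units(a_pre),
                        a_post=spec.to_trace_units(a_post),
                        plastic=plastic)


class TestSynapticCurrent:
    def test_no_input(self, lif, spec16):
        assert synaptic_current(0, 0, lif, spec16) == 0

    def test_unit_excitatory_conductance_gives_k(self, lif, spec16):
        g = spec16.to_w_units(1.0)
        assert synaptic_current(g, 0, lif, spec16) == 5800  # +58 mV

    def test_symmetric_cancellation(self, lif, spec16):
        g = spec16.to_w_units(0.7)
        assert synaptic_current(g, g, lif, spec16) == 0

    def test_inhibition_hyperpolarizes(self, lif, spec16):
        g = spec16.to_w_units(1.0)
        assert synaptic_current(0, g, lif, spec16) == -5800


class TestLIFStep:
    def test_rest_is_fixed_point(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        out = lif_step(s, 0, lif, spec16)
        assert out.v == s.v and not out.fired

    def test_single_euler_step_float(self, lif, specf):
        # v = -64, leak only: dV = -(1/100)*(v - v_rest) = -0.01
        s = NeuronState.resting(lif, specf)
        s.v = specf.to_v_units(-64.0)
        out = lif_step(s, 0.0, lif, specf)
        assert specf.from_v_units(out.v) == pytest.approx(-64.01, abs=1e-12)

    def test_single_euler_step_fixed(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        s.v = -6400
        out = lif_step(s, 0, lif, spec16)
        assert out.v == -6401

    def test_crossing_threshold_fires_and_resets_to_rest(self, lif, spec16):
        # threshold comparison applies to the updated potential: drive the
        # neuron from just below -52 mV across the threshold
        s = NeuronState.resting(lif, spec16)
        s.v = spec16.to_v_units(-52.05)
        out = lif_step(s, spec16.to_v_units(20.0), lif, spec16)
        assert out.fired and out.v == spec16.to_v_units(-65.0)

    def test_adapted_threshold_blocks_firing(self, lif, hom, spec16):
        s = NeuronState.resting(lif, spec16, homeostasis_on=True)
        s.v = spec16.to_v_units(-52.0)
        s.theta = spec16.to_v_units(2.0)
        out = lif_step(s, 0, lif, spec16)
        assert not out.fired

    def test_closed_form_linear_recurrence_float(self, lif, specf):
        """Constant subthreshold current: trajectory matches
        v_{n+1} = a v_n + b in closed form to well under 1 LSB."""
        i_mv = 10.0  # v_inf = -55 mV, below threshold
        a = 1.0 - lif.dt / lif.tau_m
        c = lif.v_rest + i_mv
        s = NeuronState.resting(lif, specf)
        i_u = specf.to_v_units(i_mv)
        for n in range(1, 2001):
            s = lif_step(s, i_u, lif, specf)
            closed = c + (a ** n) * (lif.v_rest - c)
            assert abs(specf.from_v_units(s.v) - closed) < 1e-9
            assert not s.fired


class TestConductancesAndTraces:
    def test_tau_equal_dt_removes_everything(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        s.g_ex = spec16.to_w_units(5.0)
        s.g_ih = spec16.to_w_units(1.5)
        out = decay_conductances(s, lif, spec16)
        assert out.g_ex == 0 and out.g_ih == 0

    def test_trace_decay_ten_steps_float(self, stdp, specf):
        syn = _syn(specf, a_pre=0.01)
        for _ in range(10):
            syn = decay_traces(syn, stdp, specf)
        value = syn.a_pre / specf.trace_scale
        assert value == pytest.approx(0.01 * 0.95 ** 10, rel=1e-12)
        assert value == pytest.approx(0.005987, abs=5e-7)

    def test_zero_state_stays_zero(self, stdp, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        assert decay_conductances(s, lif, spec16).g_ex == 0
        syn = _syn(spec16)
        out = decay_traces(syn, stdp, spec16)
        assert out.a_pre == 0 and out.a_post == 0

    def test_inject_accumulates(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        s.g_ex = spec16.to_w_units(0.2)
        syn = SynapseState(0, 1, w=spec16.to_w_units(0.5))
        out = inject_spike(s, syn, spec16)
        assert out.g_ex == spec16.to_w_units(0.7)

    def test_inject_zero_weight_noop(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        out = inject_spike(s, SynapseState(0, 1, w=0), spec16)
        assert out.g_ex == s.g_ex and out.g_ih == s.g_ih

    def test_simultaneous_spikes_order_independent(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        a = SynapseState(0, 2, w=spec16.to_w_units(0.3))
        b = SynapseState(1, 2, w=spec16.to_w_units(0.4))
        out1 = inject_spike(inject_spike(s, a, spec16), b, spec16)
        out2 = inject_spike(inject_spike(s, b, spec16), a, spec16)
        assert out1.g_ex == out2.g_ex == spec16.to_w_units(0.7)

    def test_inhibitory_spike_goes_to_g_ih(self, lif, spec16):
        s = NeuronState.resting(lif, spec16)
        syn = SynapseState(0, 1, w=spec16.to_w_units(1.0),
                           sign="inhibitory")
        assert inject_spike(s, syn, spec16).g_ih == spec16.to_w_units(1.0)


class TestSTDP:
    def test_pre_with_zero_post_trace_leaves_w(self, stdp, specf):
        syn = _syn(specf, w=0.5)
        out = stdp_on_pre(syn, stdp, specf)
        assert out.w == syn.w
        assert out.a_pre / specf.trace_scale == pytest.approx(0.01)

    def test_post_before_pre_depresses(self, stdp, specf):
        """Post spike 10 ms before a pre spike: w drops by 0.01*0.95^10."""
        syn = _syn(specf, w=0.5)
        syn = stdp_on_post(syn, stdp, specf)          # post fires
        for _ in range(10):
            syn = decay_traces(syn, stdp, specf)
        w_before = syn.w
        syn = stdp_on_pre(syn, stdp, specf)           # pre fires
        dw = (syn.w - w_before) / specf.weight_scale
        assert dw == pytest.approx(-0.01 * 0.95 ** 10, rel=1e-12)

    def test_pre_before_post_potentiates(self, stdp, specf):
        syn = _syn(specf, w=0.5)
        syn = stdp_on_pre(syn, stdp, specf)
        for _ in range(10):
            syn = decay_traces(syn, stdp, specf)
        w_before = syn.w
        syn = stdp_on_post(syn, stdp, specf)
        dw = (syn.w - w_before) / specf.weight_scale
        assert dw == pytest.approx(+0.01 * 0.95 ** 10, rel=1e-12)

    def test_clips_at_zero(self, stdp, specf):
        syn = _syn(specf, w=0.001, a_post=-0.01)
        assert stdp_on_pre(syn, stdp, specf).w == 0

    def test_clips_at_w_max(self, stdp, specf):
        syn = _syn(specf, w=1.0, a_pre=0.02)
        assert stdp_on_post(syn, stdp, specf).w == specf.to_w_units(1.0)

    def test_static_synapse_untouched(self, stdp, spec16):
        syn = _syn(spec16, w=0.5, a_post=-0.01, plastic=False)
        assert stdp_on_pre(syn, stdp, spec16).w == syn.w

    @given(ops=st.lists(st.sampled_from(["pre", "post", "decay"]),
                        min_size=1, max_size=60),
           w0=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_weight_always_in_bounds(self, ops, w0):
        """Plastic weights stay in [0, w_max] under arbitrary schedules,
        in both quantized and real arithmetic."""
        stdp = STDPParams()
        for spec in (FixedSpec.from_mode("fixed16"),
                     FixedSpec.from_mode("float")):
            syn = _syn(spec, w=w0)
            for op in ops:
                if op == "pre":
                    syn = stdp_on_pre(syn, stdp, spec)
                elif op == "post":
                    syn = stdp_on_post(syn, stdp, spec)
                else:
                    syn = decay_traces(syn, stdp, spec)
                assert 0 <= syn.w <= spec.to_w_units(stdp.w_max)

    def test_window_sign_and_monotonicity(self, stdp, specf):
        """Pairing at lag dt: potentiation iff pre leads, |dw| decreasing
        in |dt|, matching the trace closed form exactly."""
        def paired_dw(lag):
            syn = _syn(specf, w=0.5)
            if lag > 0:        # pre leads post by lag
                syn = stdp_on_pre(syn, stdp, specf)
                for _ in range(lag):
                    syn = decay_traces(syn, stdp, specf)
                w0 = syn.w
                syn = stdp_on_post(syn, stdp, specf)
            else:              # post leads pre by -lag
                syn = stdp_on_post(syn, stdp, specf)
                for _ in range(-lag):
                    syn = decay_traces(syn, stdp, specf)
                w0 = syn.w
                syn = stdp_on_pre(syn, stdp, specf)
            return (syn.w - w0) / specf.weight_scale

        lags = list(range(-50, 0)) + list(range(1, 51))
        dws = {lag: paired_dw(lag) for lag in lags}
        for lag, dw in dws.items():
            expected = math.copysign(0.01 * 0.95 ** abs(lag), lag)
            assert dw == pytest.approx(expected, rel=1e-9)
        for lag in range(1, 50):
            assert dws[lag] > dws[lag + 1] > 0
            assert dws[-lag] < dws[-(lag + 1)] < 0


class TestNormalization:
    def test_uniform_overshoot(self, stdp, specf):
        w = [specf.to_w_units(0.2)] * 144
        out = normalize_weights(w, stdp, specf)
        vals = [x / specf.weight_scale for x in out]
        assert vals[0] == pytest.approx(0.2 - 8.8 / 144, rel=1e-12)
        assert sum(vals) == pytest.approx(20.0, rel=1e-12)

    def test_uniform_undershoot(self, stdp, specf):
        w = [specf.to_w_units(0.01)] * 144
        out = normalize_weights(w, stdp, specf)
        vals = [x / specf.weight_scale for x in out]
        assert vals[0] == pytest.approx(0.01 + (20 - 1.44) / 144, rel=1e-12)
        assert vals[0] == pytest.approx(0.138889, abs=1e-6)

    def test_already_normalized_is_identity_fixed(self, stdp, spec16):
        target = spec16.to_w_units(20.0)
        w = [target // 144 + (1 if i < target % 144 else 0)
             for i in range(144)]
        out = normalize_weights(w, stdp, spec16)
        assert out == w

    def test_fixed_point_sum_error_bound(self, stdp, spec16):
        rng = np.random.default_rng(3)
        w = [int(x) for x in rng.integers(0, 300, size=144)]
        out = normalize_weights(w, stdp, spec16)
        # one shared rounded factor: error at most n_stdp * 0.5 LSB
        assert abs(sum(out) - spec16.to_w_units(20.0)) <= 144 * 0.5

    def test_empty_vector_rejected(self, stdp, spec16):
        with pytest.raises(ValueError):
            normalize_weights([], stdp, spec16)


class TestHomeostasis:
    def test_threshold_at_zero_theta(self, lif, spec16):
        s = NeuronState.resting(lif, spec16, homeostasis_on=True)
        assert effective_threshold(s, lif, spec16) == \
            spec16.to_v_units(-52.0)

    def test_single_spike_increment(self, lif, hom, spec16):
        s = NeuronState.resting(lif, spec16, homeostasis_on=True)
        s = theta_on_spike(s, hom, spec16)
        assert spec16.from_v_units(s.theta) == pytest.approx(0.01)

    def test_decay_factor_at_sampling_instant(self, lif, hom, specf):
        s = NeuronState.resting(lif, specf, homeostasis_on=True)
        s.theta = specf.to_v_units(5.0)
        out = theta_decay(s, hom, t_ms=10_000, spec=specf)
        assert out.theta / s.theta == pytest.approx(math.exp(-0.01),
                                                    rel=1e-12)

    def test_no_decay_off_schedule(self, lif, hom, spec16):
        s = NeuronState.resting(lif, spec16, homeostasis_on=True)
        s.theta = 500
        assert theta_decay(s, hom, t_ms=9_999, spec=spec16).theta == 500
        assert theta_decay(s, hom, t_ms=0, spec=spec16).theta == 500

    def test_disabled_neuron_never_adapts(self, lif, hom, spec16):
        s = NeuronState.resting(lif, spec16, homeostasis_on=False)
        assert theta_on_spike(s, hom, spec16).theta == 0


class TestTraceToW:
    def test_scale_ratio(self, spec16):
        # trace 0.01 (328 units) maps to 10 weight units
        assert trace_to_w(328, spec16) == 10

    def test_float_mode_exact(self, specf):
        a = specf.to_trace_units(0.0042)
        assert trace_to_w(a, specf) / specf.weight_scale == \
            pytest.approx(0.0042, rel=1e-12)
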