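"""Neuron model, propagators, ring buffers and the vectorized engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikemesh as sm
from spikemesh import snn_core as sc


class TestPropagators:
    def test_membrane_decay_matches_exponential(self):
        p = sc.compute_propagators(sc.LifParams(tau_m=10.0, h=0.1))
        assert p.p_vv == pytest.approx(math.exp(-0.01), abs=1e-12)
        assert p.p_vv == pytest.approx(0.990049834, abs=1e-9)

    def test_vanishing_timestep_limit(self):
        p = sc.compute_propagators(sc.LifParams(h=1e-9))
        assert p.p_vv == pytest.approx(1.0, abs=1e-9)
        assert abs(p.p_ve) < 1e-9 and abs(p.p_vi) < 1e-9 and abs(p.p_dc) < 1e-9

    def test_degenerate_tau_limit_is_continuous(self):
        # the tau_syn == tau_m branch must equal the limit of the general form
        base = sc.LifParams(tau_m=10.0, tau_syn_exc=10.0)
        exact = sc.compute_propagators(base).p_ve
        for eps in (1e-6, -1e-6):
            nearby = sc.compute_propagators(
                sc.LifParams(tau_m=10.0, tau_syn_exc=10.0 * (1 + eps)))
            assert nearby.p_ve == pytest.approx(exact, rel=1e-4)

    def test_recomputation_is_bit_identical(self):
        params = sc.LifParams()
        assert sc.compute_propagators(params) == sc.compute_propagators(params)

    @pytest.mark.parametrize("bad", [
        dict(tau_m=0.0), dict(tau_syn_exc=-1.0), dict(C_m=0.0),
        dict(h=0.0), dict(V_reset=-50.0, V_th=-50.0), dict(t_ref=-1.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(sc.InvalidParameterError):
            sc.LifParams(**bad)


class TestStepNeuron:
    def test_resting_state_is_a_fixed_point(self):
        params = sc.LifParams(I_dc=0.0)
        prop = sc.compute_propagators(params)
        state = sc.NeuronState(v_m=params.E_L)
        for _ in range(100):
            state, spiked = sc.step_neuron(state, prop, params, 0.0, 0.0)
            assert not spiked
        assert state.v_m == params.E_L
        assert state.i_exc == 0.0 and state.i_inh == 0.0

    def test_suprathreshold_start_spikes_and_resets(self):
        params = sc.LifParams(t_ref=2.0, h=0.1)
        prop = sc.compute_propagators(params)
        state = sc.NeuronState(v_m=params.V_th + 5.0)
        state, spiked = sc.step_neuron(state, prop, params, 0.0, 0.0)
        assert spiked
        assert state.v_m == params.V_reset
        assert state.refr_steps == 20

    def test_free_decay_matches_analytic_solution(self):
        # single current pulse at t=0, then free decay: the discrete states
        # must sit on the continuous two-exponential solution at grid points
        params = sc.LifParams(I_dc=0.0)
        prop = sc.compute_propagators(params)
        w = 100.0  # pA
        state = sc.NeuronState(v_m=params.E_L)
        state, _ = sc.step_neuron(state, prop, params, w, 0.0)  # inject
        tau_m, tau_s, c = params.tau_m, params.tau_syn_exc, params.C_m
        b = tau_m * tau_s / (c * (tau_s - tau_m))
        for n in range(1, 200):
            state, spiked = sc.step_neuron(state, prop, params, 0.0, 0.0)
            assert not spiked
            t = n * params.h
            v_expected = params.E_L + w * b * (
                math.exp(-t / tau_s) - math.exp(-t / tau_m))
            assert state.v_m == pytest.approx(v_expected, abs=1e-6)

    def test_one_step_refractory_allows_firing_every_step(self):
        # the autospike construction: t_ref = h plus saturating drive
        params = sc.LifParams(t_ref=0.1, I_dc=50_000.0)
        prop = sc.compute_propagators(params)
        state = sc.NeuronState(v_m=params.V_reset)
        fired = []
        for _ in range(50):
            state, spiked = sc.step_neuron(state, prop, params, 0.0, 0.0)
            fired.append(spiked)
        assert all(fired)


class TestFixedPoint:
    def test_encode_decode_roundtrip(self, rng):
        for pa in rng.uniform(-30000, 30000, size=200):
            raw = sc.encode_weight(pa)
            assert sc.encode_weight(sc.decode_weight(raw)) == raw

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(OverflowError):
            sc.encode_weight(40_000.0)


class TestRingBuffer:
    def test_same_slot_accumulation_is_exact(self):
        rb = sc.RingBuffer()
        sc.accumulate_spike(rb, 3, sc.FixedPointWeight(100), True)
        sc.accumulate_spike(rb, 3, sc.FixedPointWeight(-30), True)
        assert rb.exc_slots[3] == 70

    def test_lumping_equivalence(self):
        k, w = 7, 1234
        rb1, rb2 = sc.RingBuffer(), sc.RingBuffer()
        for _ in range(k):
            sc.accumulate_spike(rb1, 5, sc.FixedPointWeight(w), True)
        sc.accumulate_spike(rb2, 5, sc.FixedPointWeight(k * w), True)
        assert np.array_equal(rb1.exc_slots, rb2.exc_slots)

    @pytest.mark.parametrize("delay,exc", [(0, True), (65, True), (33, False)])
    def test_delay_bounds(self, delay, exc):
        with pytest.raises(sc.DelayOverflowError):
            sc.accumulate_spike(sc.RingBuffer(), delay, sc.FixedPointWeight(1), exc)

    def test_delay_semantics_and_zero_after_read(self):
        rb = sc.RingBuffer()
        sc.accumulate_spike(rb, 3, sc.FixedPointWeight(sc.encode_weight(10.0)), True)
        outs = [sc.advance_ring(rb)[0] for _ in range(4)]
        assert outs[:2] == [0.0, 0.0]
        assert outs[2] == pytest.approx(10.0)
        assert outs[3] == 0.0  # slot was zeroed after the read

    def test_empty_buffer_reads_zero(self):
        assert sc.advance_ring(sc.RingBuffer()) == (0.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 64), st.integers(-1000, 1000)),
                    min_size=0, max_size=40),
           st.randoms(use_true_random=False))
    def test_order_independence_and_conservation(self, deliveries, pyrandom):
        rb1, rb2 = sc.RingBuffer(), sc.RingBuffer()
        shuffled = list(deliveries)
        pyrandom.shuffle(shuffled)
        for seq, rb in ((deliveries, rb1), (shuffled, rb2)):
            for delay, raw in seq:
                sc.accumulate_spike(rb, delay, sc.FixedPointWeight(raw), True)
        assert np.array_equal(rb1.exc_slots, rb2.exc_slots)
        total = sum(sc.advance_ring(rb1)[0] for _ in range(64))
        expected = sum(raw for _, raw in deliveries) * sc.DEFAULT_WEIGHT_SCALE
        assert total == pytest.approx(expected, abs=1e-9)

    def test_accumulator_overflow_is_an_error(self):
        rb = sc.RingBuffer()
        sc.accumulate_spike(rb, 1, sc.FixedPointWeight(2**31 - 1), True)
        with pytest.raises(sc.AccumulatorOverflowError):
            sc.accumulate_spike(rb, 1, sc.FixedPointWeight(1), True)


class TestNetworkEngine:
    def test_silent_network_stays_silent(self):
        from spikemesh.calibration import make_silent_net

        net = make_silent_net(5, (1, 1)).network
        raster = sm.run_network(net, 10_000, mode="fixed")
        assert raster.n_spikes == 0

    def test_fixed_vs_double_reference_agreement(self):
        # ~100-neuron network over 1,000 steps: identical spike trains up to
        # the first chaotic divergence, total counts within 2%
        net = sm.generate_microcircuit(0.0013, 0.0013, seed=7)
        assert 80 <= net.n_neurons <= 120
        fx = sm.run_network(net, 1000, mode="fixed")
        db = sm.run_network(net, 1000, mode="double")
        per_step_fx = [set(fx.neuron[fx.step == t]) for t in range(1000)]
        per_step_db = [set(db.neuron[db.step == t]) for t in range(1000)]
        diverged = [t for t in range(1000) if per_step_fx[t] != per_step_db[t]]
        first = diverged[0] if diverged else 1000
        assert per_step_fx[:first] == per_step_db[:first]
        assert first > 0
        assert abs(fx.n_spikes - db.n_spikes) / db.n_spikes < 0.02

    def test_raster_is_deterministic(self, small_net, small_raster):
        again = sm.run_network(small_net, 2000, mode="fixed")
        assert np.array_equal(again.neuron, small_raster.neuron)
        assert np.array_equal(again.step, small_raster.step)
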