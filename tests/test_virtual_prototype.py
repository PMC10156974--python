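"""Discrete-event cluster model: timing formulas, protocol, workloads."""

import numpy as np
import pytest

import spikemesh as sm
from spikemesh import virtual_prototype as vp
from spikemesh.calibration import (
    MAX_DRIVE_PA,
    _autospike_lif,
    _uniform_network,
    make_autospike_net,
    make_memory_sweep_net,
    make_silent_net,
)
from spikemesh import connectome as cx


PERF = sm.PerfParams()


class TestTimingFormulas:
    def test_full_worker_compute_time(self):
        assert sm.worker_compute_time(255, PERF) / 1e3 == pytest.approx(1.505, abs=0.01)

    def test_single_neuron_compute_time(self):
        assert sm.worker_compute_time(1, PERF) == pytest.approx(31 / 189.383 * 1e3,
                                                               rel=1e-12)

    def test_occupancy_difference_is_254_clock_periods(self):
        diff = sm.worker_compute_time(255, PERF) - sm.worker_compute_time(1, PERF)
        assert diff == pytest.approx(254 * 1e3 / 189.383, rel=1e-12)

    def test_npw_bounds(self):
        with pytest.raises(ValueError):
            sm.worker_compute_time(0, PERF)
        with pytest.raises(ValueError):
            sm.worker_compute_time(256, PERF)

    def test_memory_latency_only(self):
        assert sm.memory_access_time(0, PERF) == pytest.approx(800.0)

    def test_memory_transfer_example(self):
        # 8,000 bytes: 800 ns latency + 800 ns transfer = 1,600 ns, i.e. an
        # apparent mean bandwidth of 5 GB/s
        t = sm.memory_access_time(8000, PERF)
        assert t == pytest.approx(1600.0)
        assert 8000 / t == pytest.approx(5.0)  # bytes/ns == GB/s

    def test_memory_time_increases_with_size(self):
        sizes = np.arange(0, 10_000, 500)
        times = [sm.memory_access_time(s, PERF) for s in sizes]
        assert np.all(np.diff(times) > 0)

    def test_acceleration_arithmetic(self):
        tl = vp.EventTimeline(9_000_000, 0.1, 45.0, {}, {}, {}, {}, {}, 0)
        assert sm.predict_acceleration(tl) == pytest.approx(20.0)
        tl2 = vp.EventTimeline(1000, 0.1, 1000 * 0.1e-3, {}, {}, {}, {}, {}, 0)
        assert sm.predict_acceleration(tl2) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sm.predict_acceleration(vp.EventTimeline(10, 0.1, 0.0, {}, {}, {}, {}, {}, 0))

    def test_acceleration_halves_when_steps_double(self):
        tl = vp.EventTimeline(1000, 0.1, 2.0, {}, {}, {}, {}, {}, 0)
        slower = vp.EventTimeline(1000, 0.1, 4.0, {}, {}, {}, {}, {}, 0)
        assert sm.predict_acceleration(slower) == pytest.approx(
            sm.predict_acceleration(tl) / 2)


def _run(cfg, perf=PERF, n_steps=100, **kw):
    return vp.simulate(cfg.network, cfg.mapping, cfg.topology, perf, n_steps, **kw)


class TestStepTiming:
    def test_silent_single_node_constant_duration(self):
        tl, _ = _run(make_silent_net(1, (1, 1)), collect_raster=False)
        starts = tl.step_starts[0]
        durations = np.diff(starts)
        assert np.ptp(durations) < 1e-9  # no trend, no jitter
        assert durations[0] == pytest.approx(755.0, abs=0.1)

    def test_single_node_duration_ignores_link_parameters(self):
        import dataclasses

        slow_links = sm.Topology(1, 1, row_latency_ns=1e6, col_latency_ns=1e6)
        cfg = make_silent_net(3, (1, 1))
        cfg2 = dataclasses.replace(cfg, topology=slow_links)
        t1, _ = _run(cfg, collect_raster=False)
        t2, _ = _run(cfg2, collect_raster=False)
        assert t1.mean_step_ns(0) == pytest.approx(t2.mean_step_ns(0))

    def test_two_node_adds_one_link_latency(self):
        t1, _ = _run(make_silent_net(1, (1, 1)), collect_raster=False)
        t2, _ = _run(make_silent_net(1, (2, 1)), collect_raster=False)
        assert t2.mean_step_ns(0) - t1.mean_step_ns(0) == pytest.approx(794.0, abs=0.5)


class TestFunctionalMode:
    def test_spike_trains_match_pure_engine(self, small_net):
        ref = sm.run_network(small_net, 1500, mode="fixed")
        mapping = sm.map_round_robin(small_net.n_neurons, 4)
        _, ras = vp.simulate(small_net, mapping, sm.Topology(2, 2), PERF,
                             1500, mode="functional", seed=0)
        assert np.array_equal(ref.neuron, ras.neuron)
        assert np.array_equal(ref.step, ras.step)

    def test_performance_parameters_never_alter_function(self, small_net):
        mapping = sm.map_round_robin(small_net.n_neurons, 4)
        topo = sm.Topology(2, 2)
        rng = np.random.default_rng(42)
        baseline = None
        for _ in range(3):
            perf = sm.PerfParams(
                f_clk_mhz=float(rng.uniform(50, 400)),
                mem_t_lat_ns=float(rng.uniform(100, 5000)),
                ringbuffer_bw_gbs=float(rng.uniform(0.1, 5)),
                spike_local_cost_ns=float(rng.uniform(0, 500)),
                step_overhead_ns=float(rng.uniform(0, 2000)),
            )
            _, ras = vp.simulate(small_net, mapping, topo, perf, 800, seed=0)
            key = (ras.neuron.tobytes(), ras.step.tobytes())
            baseline = baseline or key
            assert key == baseline

    def test_timeline_and_raster_deterministic(self, small_net):
        mapping = sm.map_round_robin(small_net.n_neurons, 4)
        runs = [vp.simulate(small_net, mapping, sm.Topology(2, 2), PERF, 500,
                            seed=0) for _ in range(2)]
        (t1, r1), (t2, r2) = runs
        assert t1.tau_s == t2.tau_s
        for k in t1.step_starts:
            assert np.array_equal(t1.step_starts[k], t2.step_starts[k])
        assert np.array_equal(r1.neuron, r2.neuron)

    def test_inconsistent_mapping_rejected(self, small_net):
        mapping = sm.map_round_robin(small_net.n_neurons + 5, 4)
        with pytest.raises(ValueError):
            vp.simulate(small_net, mapping, sm.Topology(2, 2), PERF, 10)


def _one_shot_two_hop_net():
    """One always-firing source on node 0 of a 7x5 grid with a single
    delay-1 synapse onto a neuron hosted on a two-hop-distant node."""
    n = 70
    conn = cx.Connectome(
        indptr=np.cumsum(np.concatenate([[0], [1], np.zeros(n - 1)])).astype(np.int64),
        targets=np.array([17]), delay_steps=np.array([1], dtype=np.uint8),
        weight_raw=np.array([100], dtype=np.int32),
        is_exc_source=np.ones(n, dtype=bool))
    net = _uniform_network(n, _autospike_lif(), v0=-65.0, dc=MAX_DRIVE_PA,
                           connectome=conn)
    net.dc[1:] = 0.0
    return net


class TestSynchronization:
    def test_too_few_syncs_produce_late_spikes(self):
        net = _one_shot_two_hop_net()
        mapping = sm.map_round_robin(net.n_neurons, 35)
        tl, _ = vp.simulate(net, mapping, sm.Topology(7, 5),
                            sm.PerfParams(sync_count=1), 50, seed=0,
                            collect_raster=False)
        assert tl.total_late_spikes > 0

    def test_worst_case_sync_count_never_late(self):
        net = _one_shot_two_hop_net()
        mapping = sm.map_round_robin(net.n_neurons, 35)
        tl, _ = vp.simulate(net, mapping, sm.Topology(7, 5),
                            sm.PerfParams(sync_count=2), 50, seed=0,
                            collect_raster=False)
        assert tl.total_late_spikes == 0


class TestMemoryAndRouting:
    def test_autapse_lookup_converges_to_ring_buffer_bandwidth(self):
        cfg = make_memory_sweep_net(1, 8000, "autapse")
        tl, _ = _run(cfg, n_steps=50, collect_raster=False)
        n_access = 50  # one spike per step
        mean_access_ns = tl.mem_busy_ns[0] / n_access
        bw = 8000 * 8 / mean_access_ns  # bytes per ns == GB/s
        assert bw == pytest.approx(1.5, rel=0.1)

    def test_even_long_lists_reach_90pct_of_memory_bandwidth(self):
        cfg = make_memory_sweep_net(8, 10_000, "even")
        tl, _ = _run(cfg, n_steps=30, collect_raster=False)
        total_bytes = tl.bytes_read[0]
        bw = total_bytes / (tl.tau_s * 1e9)
        assert bw >= 0.9 * PERF.mem_bw_gbs

    def test_zero_fanout_spike_reads_nothing(self):
        cfg = make_autospike_net(1, 0, (1, 1))
        tl, _ = _run(cfg, n_steps=50, collect_raster=False)
        assert tl.bytes_read[0] == 0

    def test_bytes_per_access_equals_padded_list(self):
        cfg = make_memory_sweep_net(2, 500, "even")
        tl, _ = _run(cfg, n_steps=20, collect_raster=False)
        assert tl.bytes_read[0] == 2 * 500 * 8 * 20


class TestStatisticalMode:
    def test_ingress_matches_static_estimator(self):
        topo = sm.Topology(5, 5)
        mapping = sm.map_round_robin(250, 25)
        tl, _ = vp.simulate(None, mapping, topo, PERF, 400,
                            mode="statistical", seed=7, rate_hz=100.0,
                            lookup_bytes=800)
        accel = tl.predicted_acceleration
        rep = sm.static_bandwidth(topo, mapping.loads(), 100.0, accel, 128)
        dyn = np.array([tl.ingress_gbps(k) for k in range(25)])
        rel = np.abs(dyn / rep.per_node_ingress_gbps - 1)
        assert rel.max() < 0.05

    def test_statistical_runs_are_seed_deterministic(self):
        mapping = sm.map_round_robin(100, 4)
        args = (None, mapping, sm.Topology(2, 2), PERF, 100)
        kw = dict(mode="statistical", rate_hz=50.0, lookup_bytes=400)
        t1, _ = vp.simulate(*args, seed=3, **kw)
        t2, _ = vp.simulate(*args, seed=3, **kw)
        t3, _ = vp.simulate(*args, seed=4, **kw)
        assert t1.tau_s == t2.tau_s
        assert t1.tau_s != t3.tau_s
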