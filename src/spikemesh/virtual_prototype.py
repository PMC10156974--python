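"""Discrete-event performance model of the FPGA cluster.

Each node of the row/column-connected grid is modeled as: a bank of parallel
workers updating its neurons in a fixed-depth pipeline, two DRAM channels
serving padded synaptic-list lookups, a local router streaming looked-up
records into per-worker ring buffers, serial point-to-point links to every
row/column neighbor, and the two-phase neighbor-to-neighbor synchronization
protocol.  Messages and memory requests are atomic events with start/finish
times; there is no cycle-level pipeline modeling beyond the worker formula.

Two workload modes share the same timing machinery:

``functional``
    Every node runs the real neuron dynamics (the same vectorized kernel as
    :func:`spikemesh.snn_core.run_network`) on its round-robin share of the
    network, so the produced spike trains are bit-identical to the standalone
    engine for *any* performance parameters — timing never alters function.

``statistical``
    Nodes draw per-step spike counts from a Bernoulli/binomial model at a
    configured biological rate; only timing is simulated.

Synchronization protocol: after computing a timestep each node sends a
phase-1 sync packet to every neighbor, ordered after its last spike on that
link; once a node holds phase-1 packets from all neighbors it emits phase-2.
A node starts its next timestep only when it has the final-phase sync of the
previous step from every neighbor and its local lookup pipeline has drained.
With ``sync_count`` equal to the worst-case hop count (2 on a 2-D grid) this
guarantees timely arrival of all spikes; with fewer syncs, spikes whose
ring-buffer slot has already been consumed are dropped and counted in
``late_spikes`` error registers rather than silently applied.

Determinism: simultaneous events are ordered by (time, kind priority with
sync > spike > compute, node id, sequence number); all randomness derives
from the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import heapq
import math

import numpy as np

from .connectome import (
    Mapping,
    Network,
    PADDING_TARGET,
    RECORD_BYTES,
    build_padded_images,
)
from .interconnect import ENCODING_OVERHEAD, Topology
from .snn_core import EXC_DEPTH, INH_DEPTH, StepKernel

__all__ = [
    "PerfParams",
    "EventTimeline",
    "NodeModel",
    "simulate",
    "memory_access_time",
    "worker_compute_time",
    "predict_acceleration",
]

_PRIO = {"sync": 0, "spike": 1, "compute": 2, "other": 3}


@dataclass(frozen=True)
class PerfParams:
    """Hardware/performance parameters of one cluster configuration.

    Defaults reproduce the calibrated evaluation platform: 189.383 MHz
    workers with a 30-stage pipeline, 10 workers x 255 neurons per node,
    two DRAM channels with 800 ns effective latency and 10 GB/s aggregate
    bandwidth, 1.5 GB/s per ring-buffer port, 6.25/6.0 Gbps row/column links
    with 794/815 ns one-way packet latency, and two syncs per timestep.
    """

    f_clk_mhz: float = 189.383
    pipeline_depth: int = 30
    n_workers: int = 10
    max_npw: int = 255
    step_overhead_ns: float = 591.3
    mem_t_lat_ns: float = 800.0
    mem_bw_gbs: float = 10.0
    mem_channels: int = 2
    ringbuffer_bw_gbs: float = 1.5
    spike_local_cost_ns: float = 43.5
    record_bytes: int = RECORD_BYTES
    msg_bits: int = 128
    encoding_overhead: float = ENCODING_OVERHEAD
    sync_count: int | None = None  # None: worst-case hop count of the grid

    def __post_init__(self) -> None:
        if self.f_clk_mhz <= 0 or self.mem_bw_gbs <= 0 or self.ringbuffer_bw_gbs <= 0:
            raise ValueError("rates must be positive")
        if self.sync_count is not None and self.sync_count < 0:
            raise ValueError("sync_count must be >= 0")

    def resolved_sync_count(self, topology: Topology) -> int:
        if self.sync_count is not None:
            return self.sync_count
        if topology.n_nodes == 1:
            return 0
        return 2 if (topology.width > 1 and topology.height > 1) else 1


def worker_compute_time(npw: int, perf: PerfParams) -> float:
    """Neuron-dynamics time of one worker in ns: (npw + pipeline) clock periods."""
    if not 1 <= npw <= perf.max_npw:
        raise ValueError(f"neurons per worker {npw} outside 1..{perf.max_npw}")
    return (npw + perf.pipeline_depth) / perf.f_clk_mhz * 1e3


def memory_access_time(n_bytes: float, perf: PerfParams) -> float:
    """Unloaded access time in ns: latency plus transfer at full bandwidth."""
    if n_bytes < 0:
        raise ValueError("n_bytes must be >= 0")
    return perf.mem_t_lat_ns + n_bytes / perf.mem_bw_gbs


def predict_acceleration(timeline: "EventTimeline", n_steps: int | None = None,
                         h_ms: float | None = None) -> float:
    """Acceleration factor a = n * h / tau (biological over wall-clock time)."""
    n = timeline.n_steps if n_steps is None else n_steps
    h = timeline.h_ms if h_ms is None else h_ms
    if timeline.tau_s <= 0:
        raise ValueError("simulated wall-clock duration must be positive")
    return n * h * 1e-3 / timeline.tau_s


@dataclass
class EventTimeline:
    """Result of one virtual-prototype run."""

    n_steps: int
    h_ms: float
    tau_s: float                      # completion time of the last node's last step
    step_starts: dict[int, np.ndarray]  # node -> start time (ns) per step
    late_spikes: dict[int, int]
    bytes_read: dict[int, int]
    spike_msgs_received: dict[int, int]
    mem_busy_ns: dict[int, float]
    n_events: int

    @property
    def total_late_spikes(self) -> int:
        return sum(self.late_spikes.values())

    @property
    def predicted_acceleration(self) -> float:
        return predict_acceleration(self)

    def mean_step_ns(self, node: int | None = None, discard: int = 1) -> float:
        """Steady-state mean per-timestep duration from consecutive starts."""
        if node is None:
            return float(np.mean([self.mean_step_ns(k, discard)
                                  for k in self.step_starts]))
        s = self.step_starts[node]
        if len(s) - discard < 2:
            raise ValueError("not enough steps to measure a duration")
        return float((s[-1] - s[discard]) / (len(s) - 1 - discard))

    def ingress_gbps(self, node: int, msg_bits: int = 128) -> float:
        return self.spike_msgs_received[node] * msg_bits / (self.tau_s * 1e9)


class NodeModel:
    """Per-node simulation state (timing and, in functional mode, dynamics)."""

    def __init__(self, node_id: int, sim: "_Simulator"):
        self.id = node_id
        self.sim = sim
        self.neighbors = sim.topology.neighbors(node_id)
        self.local_globals = sim.mapping.globals_of(node_id)
        self.n_local = len(self.local_globals)
        self.npw = math.ceil(self.n_local / sim.perf.n_workers) if self.n_local else 0
        if self.npw > sim.perf.max_npw:
            raise ValueError(
                f"node {node_id}: {self.npw} neurons per worker exceeds "
                f"max_npw={sim.perf.max_npw}")
        self.next_step = 0            # next timestep to start
        self.compute_done_step = -1
        self.sync_recv: dict[tuple[int, int], int] = {}  # (step, phase) -> count
        self.phase2_sent: set[int] = set()
        self.inflight = 0
        self.start_times = np.zeros(sim.n_steps)
        self.late_spikes = 0
        self.bytes_read = 0
        self.spike_msgs_received = 0
        self.mem_free = [0.0] * sim.perf.mem_channels
        self.mem_busy_ns = 0.0
        self.router_free = 0.0
        self.end_time = 0.0
        if sim.mode == "functional":
            self.kernel = StepKernel(sim.network, self.local_globals, mode=sim.dyn_mode)
            self.buf_e = np.zeros((EXC_DEPTH, self.n_local), dtype=np.int64)
            self.buf_i = np.zeros((INH_DEPTH, self.n_local), dtype=np.int64)
            self.image = sim.images[node_id]
            self.latched: tuple[np.ndarray, np.ndarray] | None = None
            self.is_exc = sim.network.is_excitatory()

    # -- helpers -----------------------------------------------------------

    def worker_of(self, local_idx: np.ndarray) -> np.ndarray:
        return local_idx % self.sim.perf.n_workers


class _Simulator:
    def __init__(self, network: Network | None, mapping: Mapping,
                 topology: Topology, perf: PerfParams, n_steps: int,
                 mode: str, seed: int, rate_hz: float | None,
                 lookup_bytes: float, dyn_mode: str, collect_raster: bool):
        if mode not in ("functional", "statistical"):
            raise ValueError(f"unknown mode {mode!r}")
        if mapping.n_nodes != topology.n_nodes:
            raise ValueError("mapping and topology disagree on node count")
        if mode == "functional":
            if network is None:
                raise ValueError("functional mode needs a network")
            if len(mapping.node_of) != network.n_neurons:
                raise ValueError("mapping does not cover the network")
        self.network = network
        self.mapping = mapping
        self.topology = topology
        self.perf = perf
        self.n_steps = n_steps
        self.mode = mode
        self.dyn_mode = dyn_mode
        self.seed = seed
        self.rate_hz = rate_hz or 0.0
        self.lookup_bytes = lookup_bytes
        self.collect_raster = collect_raster and mode == "functional"
        self.h = network.h if network is not None else 0.1
        self.sync_count = perf.resolved_sync_count(topology)

        if mode == "functional":
            self.images = build_padded_images(network.connectome, mapping)

        self.heap: list = []
        self.seq = 0
        self.now = 0.0
        self.n_events = 0
        self.link_free: dict[tuple[int, int], float] = {}
        self.nodes = [NodeModel(k, self) for k in range(topology.n_nodes)]
        self.raster_neuron: list[np.ndarray] = []
        self.raster_step: list[np.ndarray] = []

    # -- event machinery ---------------------------------------------------

    def schedule(self, t: float, kind: str, node: int, fn, *args) -> None:
        heapq.heappush(self.heap, (t, _PRIO[kind], node, self.seq, fn, args))
        self.seq += 1

    def run(self) -> None:
        max_events = 200_000_000
        for node in self.nodes:
            self._try_start(node, 0.0)
        while self.heap:
            self.now, _, _, _, fn, args = heapq.heappop(self.heap)
            fn(*args)
            self.n_events += 1
            if self.n_events > max_events:
                raise RuntimeError("virtual prototype exceeded its event budget "
                                   "(possible deadlock or runaway workload)")

    # -- links -------------------------------------------------------------

    def _send(self, t: float, src: int, dst: int, kind: str, fn, *args) -> None:
        axis = self.topology.axis_of(src, dst)
        bw = (self.topology.row_bandwidth_gbps if axis == "row"
              else self.topology.col_bandwidth_gbps) * self.perf.encoding_overhead
        lat = (self.topology.row_latency_ns if axis == "row"
               else self.topology.col_latency_ns)
        key = (src, dst)
        depart = max(t, self.link_free.get(key, 0.0))
        self.link_free[key] = depart + self.perf.msg_bits / bw  # bits / Gbps = ns
        self.schedule(depart + lat, kind, dst, fn, *args)

    # -- memory ------------------------------------------------------------

    def _mem_request(self, node: NodeModel, t: float, n_bytes: float,
                     sink_bw_gbs: float) -> float:
        """Issue a DRAM read; returns completion time (last byte streamed).

        One request occupies one channel; a lone request transfers at the
        full aggregate bandwidth, concurrent requests share it equally.
        Streaming into ring buffers is cut-through, so the sink bandwidth
        (number of distinct target buffers x per-buffer rate) caps the
        transfer when the targets are poorly distributed.
        """
        perf = self.perf
        ch = min(range(len(node.mem_free)), key=lambda i: node.mem_free[i])
        start = max(t, node.mem_free[ch])
        others_busy = sum(1 for i, f in enumerate(node.mem_free)
                          if i != ch and f > start)
        rate = perf.mem_bw_gbs / (1 + others_busy)
        rate = min(rate, sink_bw_gbs) if sink_bw_gbs > 0 else rate
        dur = perf.mem_t_lat_ns + n_bytes / rate
        node.mem_free[ch] = start + dur
        node.mem_busy_ns += dur
        node.bytes_read += int(n_bytes)
        return start + dur

    # -- node step lifecycle ----------------------------------------------

    def _try_start(self, node: NodeModel, t: float) -> None:
        step = node.next_step
        if step >= self.n_steps:
            return
        if step > 0:
            if node.compute_done_step != step - 1 or node.inflight > 0:
                return
            if self.sync_count >= 1 and node.neighbors:
                if node.sync_recv.get((step - 1, self.sync_count), 0) < len(node.neighbors):
                    return
        node.next_step = step + 1
        node.start_times[step] = t
        if self.mode == "functional":
            se, si = step % EXC_DEPTH, step % INH_DEPTH
            node.latched = (node.buf_e[se].copy(), node.buf_i[si].copy())
            node.buf_e[se] = 0
            node.buf_i[si] = 0
        npw = node.npw
        dur = (npw + self.perf.pipeline_depth) / self.perf.f_clk_mhz * 1e3 \
            + self.perf.step_overhead_ns
        self.schedule(t + dur, "compute", node.id, self._compute_done, node, step)

    def _compute_done(self, node: NodeModel, step: int) -> None:
        t = self.now
        node.compute_done_step = step
        node.end_time = max(node.end_time, t)

        if self.mode == "functional":
            exc_raw, inh_raw = node.latched
            local_spikes = node.kernel.step(exc_raw, inh_raw)
            spike_globals = node.local_globals[local_spikes]
            if self.collect_raster and spike_globals.size:
                self.raster_neuron.append(spike_globals)
                self.raster_step.append(np.full(spike_globals.size, step, dtype=np.int64))
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(node.id, step)))
            p = min(self.rate_hz * self.h * 1e-3, 1.0)
            k = rng.binomial(node.n_local, p) if node.n_local else 0
            spike_globals = node.local_globals[:k] if k else np.empty(0, dtype=np.int64)

        xs, ys = self.topology.coords(node.id)
        for g in spike_globals:
            g = int(g)
            # local delivery (every node holds lists for every source)
            self._receive_spike(node, g, step, t, count_msg=False)
            # stage 1: broadcast to the whole row and column
            for x in range(self.topology.width):
                if x != xs:
                    self._send(t, node.id, self.topology.node_id(x, ys), "spike",
                               self._on_spike_arrival,
                               self.topology.node_id(x, ys), g, step, node.id)
            for y in range(self.topology.height):
                if y != ys:
                    self._send(t, node.id, self.topology.node_id(xs, y), "spike",
                               self._on_spike_arrival,
                               self.topology.node_id(xs, y), g, step, node.id)
        # phase-1 sync after the last spike on each link
        if self.sync_count >= 1:
            for nb in node.neighbors:
                self._send(t, node.id, nb, "sync",
                           self._on_sync_arrival, nb, node.id, 1, step)
        self._maybe_phase2(node, step)
        self._try_start(node, t)

    def _on_spike_arrival(self, dst: int, source_global: int, origin_step: int,
                          origin_node: int) -> None:
        node = self.nodes[dst]
        t = self.now
        # stage 2: a stage-1 recipient in the source's column forwards along its row
        ox, _ = self.topology.coords(origin_node)
        x, y = self.topology.coords(dst)
        if x == ox and y != self.topology.coords(origin_node)[1]:
            for xx in range(self.topology.width):
                if xx != x:
                    self._send(t, dst, self.topology.node_id(xx, y), "spike",
                               self._on_spike_arrival,
                               self.topology.node_id(xx, y), source_global,
                               origin_step, origin_node)
        self._receive_spike(node, source_global, origin_step, t, count_msg=True)

    def _receive_spike(self, node: NodeModel, source_global: int,
                       origin_step: int, t: float, count_msg: bool) -> None:
        if count_msg:
            node.spike_msgs_received += 1
        perf = self.perf
        if self.mode == "functional":
            img = node.image
            n_bytes = img.list_len * perf.record_bytes
            tgt_row = img.target[source_global]
            real = tgt_row != PADDING_TARGET
            local_t = tgt_row[real].astype(np.int64)
            delays = img.delay[source_global][real].astype(np.int64)
            raws = img.weight[source_global][real].astype(np.int64)
            n_buffers = len(np.unique(node.worker_of(local_t))) if local_t.size else 0
        else:
            n_bytes = self.lookup_bytes
            local_t = delays = raws = None
            n_buffers = perf.n_workers
        sink = n_buffers * perf.ringbuffer_bw_gbs if n_buffers else 0.0
        # local router handles one spike per spike_local_cost (serial), then
        # dispatches the memory request; requests overlap across channels
        start = max(t, node.router_free)
        router_done = start + perf.spike_local_cost_ns
        node.router_free = router_done
        if n_bytes > 0:
            done = self._mem_request(node, router_done, n_bytes, sink)
        else:
            done = router_done
        node.inflight += 1
        self.schedule(done, "spike", node.id, self._spike_done,
                      node, source_global, origin_step, local_t, delays, raws)

    def _spike_done(self, node: NodeModel, source_global: int, origin_step: int,
                    local_t, delays, raws) -> None:
        t = self.now
        node.end_time = max(node.end_time, t)
        if self.mode == "functional" and local_t is not None and local_t.size:
            slot_steps = origin_step + delays
            late = slot_steps < node.next_step  # slot already latched/consumed
            node.late_spikes += int(late.sum())
            ok = ~late
            if ok.any():
                exc = bool(node.is_exc[source_global])
                buf, depth = (node.buf_e, EXC_DEPTH) if exc else (node.buf_i, INH_DEPTH)
                rows = slot_steps[ok] % depth
                np.add.at(buf, (rows, local_t[ok]), raws[ok])
        node.inflight -= 1
        self._try_start(node, t)

    def _maybe_phase2(self, node: NodeModel, step: int) -> None:
        """Emit phase-2 syncs once compute is done and all phase-1 are in."""
        if self.sync_count < 2 or step in node.phase2_sent or not node.neighbors:
            return
        if node.compute_done_step < step:
            return
        if node.sync_recv.get((step, 1), 0) < len(node.neighbors):
            return
        node.phase2_sent.add(step)
        for nb in node.neighbors:
            self._send(self.now, node.id, nb, "sync",
                       self._on_sync_arrival, nb, node.id, 2, step)

    def _on_sync_arrival(self, dst: int, src: int, phase: int, step: int) -> None:
        node = self.nodes[dst]
        if src not in node.neighbors:
            raise RuntimeError(f"sync from non-neighbor {src} at node {dst}")
        key = (step, phase)
        node.sync_recv[key] = node.sync_recv.get(key, 0) + 1
        node.end_time = max(node.end_time, self.now)
        if phase == 1:
            self._maybe_phase2(node, step)
        self._try_start(node, self.now)

    # -- results -----------------------------------------------------------

    def timeline(self) -> EventTimeline:
        tau_ns = max(node.end_time for node in self.nodes)
        return EventTimeline(
            n_steps=self.n_steps,
            h_ms=self.h,
            tau_s=tau_ns * 1e-9,
            step_starts={n.id: n.start_times.copy() for n in self.nodes},
            late_spikes={n.id: n.late_spikes for n in self.nodes},
            bytes_read={n.id: n.bytes_read for n in self.nodes},
            spike_msgs_received={n.id: n.spike_msgs_received for n in self.nodes},
            mem_busy_ns={n.id: n.mem_busy_ns for n in self.nodes},
            n_events=self.n_events,
        )

    def raster(self):
        from .analysis import SpikeRaster

        if not self.collect_raster:
            return None
        if self.raster_neuron:
            neuron = np.concatenate(self.raster_neuron)
            step = np.concatenate(self.raster_step)
            order = np.lexsort((neuron, step))
            neuron, step = neuron[order], step[order]
        else:
            neuron = np.empty(0, dtype=np.int64)
            step = np.empty(0, dtype=np.int64)
        return SpikeRaster(neuron=neuron, step=step,
                           n_neurons=self.network.n_neurons,
                           n_steps=self.n_steps, h=self.h)


def simulate(network: Network | None, mapping: Mapping, topology: Topology,
             perf: PerfParams, n_steps: int, mode: str = "functional",
             seed: int = 0, rate_hz: float | None = None,
             lookup_bytes: float = 0.0, dyn_mode: str = "fixed",
             collect_raster: bool = True):
    """Run the virtual prototype.

    Returns ``(EventTimeline, SpikeRaster | None)``; the raster is produced
    in functional mode only.  Fully deterministic given the seed.
    """
    sim = _Simulator(network, mapping, topology, perf, n_steps, mode, seed,
                     rate_hz, lookup_bytes, dyn_mode, collect_raster)
    sim.run()
    return sim.timeline(), sim.raster()
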