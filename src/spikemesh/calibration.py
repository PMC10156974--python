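"""Bottleneck-isolation test networks and parameter-extraction formulas.

The calibration workflow characterizes a cluster component-by-component with
networks designed to exercise exactly one mechanism at a time:

* **silent networks** — initial membrane potential at rest, no drive, no
  synapses: nothing ever spikes, so the per-timestep duration is pure
  computation (plus synchronization on multi-node grids).  Durations are
  affine in the neurons-per-worker count, ``tau_s = t_0 + tau_neuron * NpW``.
* **autospike networks** — refractory period of one timestep and a saturating
  DC drive make every neuron fire on every timestep; with fanout zero no
  memory is touched, isolating the per-spike local-routing cost.
* **memory sweep networks** — always-spiking sources with synaptic lists of
  a controlled length, targeting either all workers evenly (memory-bound) or
  only the source itself ("autapse" mode, ring-buffer-port-bound).

The extraction operations are the difference formulas that turn measured
per-timestep durations into component latencies: slope over NpW for the
per-neuron compute time, multi-node minus single-node for link latency,
per-additional-spike difference for the local spike cost, and the
access-time model ``t_mem = t_lat + n_bytes/BW_max = n_bytes/BW_mean``
solved for the memory latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, Mapping, Network, PopulationSpec, map_round_robin
from .interconnect import Topology
from .snn_core import LifParams
from .virtual_prototype import PerfParams, simulate

__all__ = [
    "CalibrationMeasurement",
    "CalibrationConfig",
    "MAX_DRIVE_PA",
    "make_silent_net",
    "make_autospike_net",
    "make_memory_sweep_net",
    "extract_tau_neuron",
    "extract_link_latency",
    "extract_spike_cost",
    "mean_memory_bandwidth",
    "extract_mem_latency",
    "measure_step_duration",
    "run_calibration_suite",
]

#: DC amplitude (pA) guaranteeing a threshold crossing within one timestep
#: from reset for the microcircuit neuron (needs ~38,000 pA; see methods note)
MAX_DRIVE_PA = 50_000.0


@dataclass(frozen=True)
class CalibrationMeasurement:
    """One measured operating point of a calibration experiment."""

    label: str
    tau_step_ns: float
    n_spikes_per_step: float = 0.0
    bytes_per_access: int = 0
    runtime_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_step_ns <= 0:
            raise ValueError("per-timestep duration must be positive")


@dataclass
class CalibrationConfig:
    """A generated test network plus its cluster placement."""

    label: str
    network: Network
    mapping: Mapping
    topology: Topology


def _empty_connectome(n: int) -> Connectome:
    return Connectome(
        indptr=np.zeros(n + 1, dtype=np.int64),
        targets=np.empty(0, dtype=np.int64),
        delay_steps=np.empty(0, dtype=np.uint8),
        weight_raw=np.empty(0, dtype=np.int32),
        is_exc_source=np.ones(n, dtype=bool),
    )


def _uniform_network(n: int, lif: LifParams, v0: float, dc: float,
                     connectome: Connectome | None) -> Network:
    pop = PopulationSpec("CAL", n, True, lif, dc)
    return Network(
        populations=[pop],
        pop_of=np.zeros(n, dtype=np.int64),
        v_init=np.full(n, v0),
        dc=np.full(n, dc),
        connectome=connectome if connectome is not None else _empty_connectome(n),
        h=lif.h,
    )


def make_silent_net(npw: int, grid: tuple[int, int] = (1, 1),
                    n_workers: int = 10) -> CalibrationConfig:
    """A network that provably never spikes: resting potential, zero drive."""
    if npw > 255:
        raise ValueError("npw exceeds the 255-neuron worker capacity")
    topo = Topology(*grid)
    n = npw * n_workers * topo.n_nodes
    lif = LifParams()
    net = _uniform_network(n, lif, v0=lif.E_L, dc=0.0, connectome=None)
    return CalibrationConfig(f"silent npw={npw} {grid[0]}x{grid[1]}", net,
                             map_round_robin(n, topo.n_nodes), topo)


def _autospike_lif() -> LifParams:
    # refractory period of one timestep + saturating drive: one spike per step
    return LifParams(t_ref=0.1, I_dc=MAX_DRIVE_PA)


def make_autospike_net(n_neurons: int, fanout: int = 0,
                       grid: tuple[int, int] = (1, 1)) -> CalibrationConfig:
    """Every neuron fires on every timestep; fanout 0 avoids memory lookups."""
    topo = Topology(*grid)
    lif = _autospike_lif()
    if fanout:
        indptr = np.arange(n_neurons + 1, dtype=np.int64) * fanout
        targets = np.tile(np.arange(n_neurons), fanout)[: n_neurons * fanout]
        targets = (np.repeat(np.arange(n_neurons), fanout)
                   + 1 + np.tile(np.arange(fanout), n_neurons)) % n_neurons
        conn = Connectome(
            indptr=indptr,
            targets=targets.astype(np.int64),
            delay_steps=np.ones(n_neurons * fanout, dtype=np.uint8),
            weight_raw=np.zeros(n_neurons * fanout, dtype=np.int32),
            is_exc_source=np.ones(n_neurons, dtype=bool),
        )
    else:
        conn = None
    net = _uniform_network(n_neurons, lif, v0=lif.V_reset, dc=MAX_DRIVE_PA,
                           connectome=conn)
    return CalibrationConfig(f"autospike n={n_neurons} fo={fanout} {grid[0]}x{grid[1]}",
                             net, map_round_robin(n_neurons, topo.n_nodes), topo)


def make_memory_sweep_net(n_parallel: int, list_len: int,
                          distribution: str = "even",
                          n_workers: int = 10) -> CalibrationConfig:
    """Single-node memory experiment: ``n_parallel`` always-spiking sources
    with padded lists of exactly ``list_len`` synapses (inert zero weights).

    ``even`` cycles targets over enough silent neurons to touch every worker
    ring buffer; ``autapse`` connects each source only to itself.
    """
    if distribution not in ("even", "autapse"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if list_len < 0:
        raise ValueError("list_len must be >= 0")
    topo = Topology(1, 1)
    lif = _autospike_lif()
    n_silent = n_workers if distribution == "even" else 0
    n = n_parallel + n_silent

    if list_len:
        indptr = np.zeros(n + 1, dtype=np.int64)
        indptr[1:n_parallel + 1] = list_len
        indptr = np.cumsum(indptr)
        if distribution == "even":
            tgt = np.concatenate([np.arange(list_len) % n for _ in range(n_parallel)])
        else:
            tgt = np.repeat(np.arange(n_parallel), list_len)
        conn = Connectome(
            indptr=indptr,
            targets=tgt.astype(np.int64),
            delay_steps=np.ones(n_parallel * list_len, dtype=np.uint8),
            weight_raw=np.zeros(n_parallel * list_len, dtype=np.int32),
            is_exc_source=np.ones(n, dtype=bool),
        )
    else:
        conn = None

    # silent padding targets: keep them below threshold by removing the drive
    net = _uniform_network(n, lif, v0=lif.V_reset, dc=MAX_DRIVE_PA, connectome=conn)
    if n_silent:
        net.v_init[n_parallel:] = lif.E_L
        net.dc[n_parallel:] = 0.0
    return CalibrationConfig(f"memsweep n={n_parallel} L={list_len} {distribution}",
                             net, map_round_robin(n, 1), topo)


# ---------------------------------------------------------------------------
# extraction formulas
# ---------------------------------------------------------------------------

def extract_tau_neuron(tau_a: float, tau_b: float, npw_a: int, npw_b: int) -> float:
    """Per-neuron compute time: duration slope over neurons-per-worker."""
    if npw_a == npw_b:
        raise ValueError("need two distinct NpW operating points")
    return (tau_b - tau_a) / (npw_b - npw_a)


def extract_link_latency(tau_multi: float, tau_single: float) -> float:
    """One-way packet latency: multi-node minus single-node step duration."""
    return tau_multi - tau_single


def extract_spike_cost(tau_spiking: float, tau_baseline: float,
                       n_spikes_delta: int) -> float:
    """Per-spike local cost from the duration increase per additional spike."""
    if n_spikes_delta < 1:
        raise ValueError("need at least one additional spike per step")
    return (tau_spiking - tau_baseline) / n_spikes_delta


def mean_memory_bandwidth(total_bytes: float, runtime_s: float) -> float:
    """Bytes read over the whole run divided by its runtime, in GB/s."""
    if runtime_s <= 0:
        raise ValueError("runtime must be positive")
    return total_bytes / runtime_s / 1e9


def extract_mem_latency(n_bytes: float, bw_mean_gbs: float, bw_max_gbs: float) -> float:
    """Memory latency (ns) from the access-time model:
    t_lat = n_bytes * (1/BW_mean - 1/BW_max)."""
    if bw_mean_gbs >= bw_max_gbs:
        raise ValueError("mean bandwidth must lie below the maximum")
    if bw_mean_gbs <= 0:
        raise ValueError("mean bandwidth must be positive")
    return n_bytes * (1.0 / bw_mean_gbs - 1.0 / bw_max_gbs)


# ---------------------------------------------------------------------------
# virtual-prototype measurement harness
# ---------------------------------------------------------------------------

def measure_step_duration(cfg: CalibrationConfig, perf: PerfParams,
                          n_steps: int = 200, seed: int = 0) -> CalibrationMeasurement:
    """Run a calibration network on the virtual prototype and return the
    steady-state mean per-timestep duration of node 0."""
    timeline, _ = simulate(cfg.network, cfg.mapping, cfg.topology, perf,
                           n_steps, mode="functional", seed=seed,
                           collect_raster=False)
    return CalibrationMeasurement(
        label=cfg.label,
        tau_step_ns=timeline.mean_step_ns(node=0),
        bytes_per_access=0,
        runtime_s=timeline.tau_s,
    )


def run_calibration_suite(perf: PerfParams | None = None, n_steps: int = 200,
                          seed: int = 0) -> dict:
    """Reproduce the bottleneck-isolation experiments on the virtual
    prototype and extract the component parameters from the measurements.

    Returns a dict with the raw measurements and the extracted values
    (``tau_neuron_ns``, ``t0_ns``, ``link_row_ns``, ``link_col_ns``,
    ``spike_cost_ns``, ``mem_bw_mean_gbs``, ``mem_t_lat_ns``), alongside the
    injected ground truth for comparison.
    """
    perf = perf or PerfParams()

    def tau(cfg):
        return measure_step_duration(cfg, perf, n_steps, seed).tau_step_ns

    # computational bottleneck: silent nets, NpW sweep on one node
    tau_s1 = tau(make_silent_net(1, (1, 1), perf.n_workers))
    tau_s255 = tau(make_silent_net(255, (1, 1), perf.n_workers))
    tau_neuron = extract_tau_neuron(tau_s1, tau_s255, 1, 255)
    t0 = tau_s1 - tau_neuron * 1

    # network latencies: silent nets on 2x1 (row axis) and 1x2 (column axis)
    tau_row = tau(make_silent_net(1, (2, 1), perf.n_workers))
    tau_col = tau(make_silent_net(1, (1, 2), perf.n_workers))
    link_row = extract_link_latency(tau_row, tau_s1)
    link_col = extract_link_latency(tau_col, tau_s1)

    # local communication: autospike fanout-0 nets, 1 vs 20 spiking neurons
    tau_a1 = tau(make_autospike_net(1, 0, (1, 1)))
    tau_a20 = tau(make_autospike_net(20, 0, (1, 1)))
    spike_cost = extract_spike_cost(tau_a20, tau_a1, 19)

    # memory: single always-spiking source, 1,000-synapse even list; the
    # access time is the duration increase over a compute-matched silent net
    # minus the serial router slot
    list_len = 1000
    sweep = make_memory_sweep_net(1, list_len, "even", perf.n_workers)
    npw_match = sweep.mapping.loads().max()
    npw_match = int(np.ceil(npw_match / perf.n_workers))
    tau_mem = tau(sweep)
    tau_base = tau(make_silent_net(npw_match, (1, 1), perf.n_workers))
    n_bytes = list_len * perf.record_bytes
    t_access = tau_mem - tau_base - perf.spike_local_cost_ns
    bw_mean = n_bytes / t_access  # bytes per ns == GB/s
    t_lat = extract_mem_latency(n_bytes, bw_mean, perf.mem_bw_gbs)

    return {
        "measurements": {
            "silent_1x1_npw1_ns": tau_s1,
            "silent_1x1_npw255_ns": tau_s255,
            "silent_2x1_npw1_ns": tau_row,
            "silent_1x2_npw1_ns": tau_col,
            "autospike_1_ns": tau_a1,
            "autospike_20_ns": tau_a20,
            "memsweep_L1000_ns": tau_mem,
            "memsweep_baseline_ns": tau_base,
        },
        "extracted": {
            "tau_neuron_ns": tau_neuron,
            "t0_ns": t0,
            "link_row_ns": link_row,
            "link_col_ns": link_col,
            "spike_cost_ns": spike_cost,
            "mem_bw_mean_gbs": bw_mean,
            "mem_t_lat_ns": t_lat,
        },
        "injected": {
            "tau_neuron_ns": 1e3 / perf.f_clk_mhz,
            "link_row_ns": None,  # filled from topology defaults below
            "link_col_ns": None,
            "spike_cost_ns": perf.spike_local_cost_ns,
            "mem_t_lat_ns": perf.mem_t_lat_ns,
        },
    }
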