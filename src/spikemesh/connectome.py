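"""Population-structured random networks and the padded synaptic-list image.

This module generates scaled versions of the cortical microcircuit — the
full-density model of 1 mm^2 of early sensory cortex with 77,169 LIF neurons
in eight populations (L2/3E/I, L4E/I, L5E/I, L6E/I) connected by ~0.3 billion
synapses — and lays the resulting connectome out the way the cluster stores
it: neurons assigned to nodes round-robin, synapses grouped into per-source
lists padded to a single common length so that the DRAM address of any list
is pure arithmetic (source index × list length × 8 bytes), with no lookup
table.

Each stored synapse record is 64 bits: a 16-bit node-local target index, an
8-bit delay in timesteps, one alignment pad byte and a 32-bit fixed-point
weight (56 bits of payload).  ``target_id == 0xFFFF`` marks padding entries.

Connectivity model
------------------
Synapses are drawn pairwise-Bernoulli.  The published microcircuit draws a
fixed total number of synapses K(p) = ln(1-p)/ln(1-1/(Ns*Nt)) per projection
(which permits multapses); we use effective pairwise probabilities
``p_eff = K(p)/(Ns*Nt)`` so that expected projection sizes — and hence the
mean fanout of ~3,880 and the ~0.3e9 total — match the published model.

Downscaling
-----------
``neuron_scale`` multiplies population sizes; ``synapse_scale`` multiplies
the expected in-degree.  When in-degree is reduced, synaptic weights are
scaled by 1/sqrt(synapse_scale) and the lost mean recurrent input is
replaced by a compensating DC current computed from the published full-scale
population rates — the established downscaling recipe for this model.
External Poisson drive is emulated by its DC mean (K_ext * 8 Hz * tau_syn *
w), as in the reference implementation with Poisson input switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import struct
import warnings

import numpy as np

from .snn_core import (
    DEFAULT_WEIGHT_SCALE,
    EXC_DEPTH,
    INH_DEPTH,
    LifParams,
    encode_weight,
)

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "Connectome",
    "Network",
    "Mapping",
    "SynapseRecord",
    "PaddedListImage",
    "PADDING_TARGET",
    "RECORD_BYTES",
    "microcircuit_connectivity",
    "microcircuit_populations",
    "generate_microcircuit",
    "expected_synapse_matrix",
    "expected_total_synapses",
    "expected_mean_fanout",
    "estimate_padded_list_len",
    "estimate_image_bytes_per_node",
    "map_round_robin",
    "build_padded_images",
    "encode_record",
    "decode_record",
    "lookup",
    "psp_to_psc",
]

PADDING_TARGET = 0xFFFF
RECORD_BYTES = 8

# --- published microcircuit constants --------------------------------------

POP_NAMES = ("L23E", "L23I", "L4E", "L4I", "L5E", "L5I", "L6E", "L6I")
POP_SIZES = np.array([20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948])
POP_EXC = np.array([True, False, True, False, True, False, True, False])

# connection probabilities, rows = target population, cols = source population
CONN_PROB = np.array([
    [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0,    0.0076, 0.0],
    [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0,    0.0042, 0.0],
    [0.0077, 0.0059, 0.0497, 0.135,  0.0067, 0.0003, 0.0453, 0.0],
    [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0,    0.1057, 0.0],
    [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0],
    [0.0548, 0.0269, 0.0257, 0.0022, 0.06,   0.3158, 0.0086, 0.0],
    [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],
    [0.0364, 0.001,  0.0034, 0.0005, 0.0277, 0.008,  0.0658, 0.1443],
])

#: in-degrees of external (thalamo-cortical/background) drive per population
K_EXT = np.array([1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100])
BG_RATE_HZ = 8.0

#: published full-scale mean firing rates (Hz), used for DC compensation
FULL_MEAN_RATES = np.array([0.971, 2.868, 4.746, 5.396, 8.142, 9.078, 0.991, 7.523])

PSP_EXC_MV = 0.15          # unitary excitatory PSP amplitude
G_REL_INHIBITION = -4.0    # inhibitory/excitatory weight ratio
W_REL_SD = 0.1             # relative sd of weights
DELAY_EXC_MS = (1.5, 0.75)  # mean, sd
DELAY_INH_MS = (0.75, 0.375)
V_INIT_MEAN_MV = -58.0
V_INIT_SD_MV = 10.0


def psp_to_psc(psp_mv: float, params: LifParams | None = None) -> float:
    """Peak synaptic current (pA) producing a given unitary PSP amplitude."""
    p = params or LifParams()
    tau_m, tau_s, c_m = p.tau_m, p.tau_syn_exc, p.C_m
    if tau_m == tau_s:
        v_max = tau_m / (c_m * math.e)
    else:
        t_max = math.log(tau_m / tau_s) / (1 / tau_s - 1 / tau_m)
        v_max = (
            tau_m * tau_s / (c_m * (tau_s - tau_m))
            * (math.exp(-t_max / tau_s) - math.exp(-t_max / tau_m))
        )
    return psp_mv / v_max


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    is_excitatory: bool
    lif: LifParams
    dc_amplitude: float  # pA

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("population size must be non-negative")


@dataclass
class ConnectivitySpec:
    """Pairwise connection statistics (target-pop rows, source-pop cols)."""

    conn_prob: np.ndarray
    weight_mean: np.ndarray  # pA
    weight_sd: np.ndarray    # pA
    delay_mean: np.ndarray   # ms, per source population
    delay_sd: np.ndarray     # ms
    delay_min: float = 0.1   # ms

    def __post_init__(self) -> None:
        p = np.asarray(self.conn_prob, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("connection probabilities must lie in [0, 1]")


@dataclass
class Connectome:
    """Synapses in CSR-by-source layout."""

    indptr: np.ndarray       # (n_neurons + 1,)
    targets: np.ndarray      # (n_synapses,) global target ids
    delay_steps: np.ndarray  # (n_synapses,) uint8, >= 1
    weight_raw: np.ndarray   # (n_synapses,) int32 fixed point
    is_exc_source: np.ndarray  # (n_neurons,) bool

    @property
    def n_neurons(self) -> int:
        return len(self.indptr) - 1

    @property
    def n_synapses(self) -> int:
        return int(self.indptr[-1])

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def outgoing(self, sources: np.ndarray):
        """Concatenated synapse arrays of the given sources.

        Returns (targets, delays, raw_weights, exc_mask) where ``exc_mask``
        flags synapses whose source is excitatory.
        """
        sources = np.asarray(sources)
        starts = self.indptr[sources]
        ends = self.indptr[sources + 1]
        counts = ends - starts
        if counts.sum() == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.uint8), e.astype(np.int64), e.astype(bool)
        idx = np.concatenate([np.arange(s, t) for s, t in zip(starts, ends)])
        exc = np.repeat(self.is_exc_source[sources], counts)
        return (
            self.targets[idx].astype(np.int64),
            self.delay_steps[idx].astype(np.int64),
            self.weight_raw[idx].astype(np.int64),
            exc,
        )


@dataclass
class Network:
    """A complete simulable network: populations, state init, drive, synapses."""

    populations: list[PopulationSpec]
    pop_of: np.ndarray      # (n,) population index per neuron
    v_init: np.ndarray      # (n,) mV
    dc: np.ndarray          # (n,) pA (overrides/extends population dc)
    connectome: Connectome | None
    h: float = 0.1
    weight_scale: float = DEFAULT_WEIGHT_SCALE

    @property
    def n_neurons(self) -> int:
        return len(self.pop_of)

    def is_excitatory(self) -> np.ndarray:
        exc = np.array([p.is_excitatory for p in self.populations])
        return exc[self.pop_of]


# ---------------------------------------------------------------------------
# expected-count arithmetic (analytic; no sampling)
# ---------------------------------------------------------------------------

def _k_multapse(p: np.ndarray, n_src: np.ndarray, n_tgt: np.ndarray) -> np.ndarray:
    """Expected synapse count of the published fixed-total-number model."""
    pairs = np.outer(n_tgt, n_src).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.log1p(-p) / np.log1p(-1.0 / pairs)
    k[p == 0] = 0.0
    return k


def effective_probabilities(
    neuron_scale: float = 1.0, synapse_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled population sizes and effective pairwise Bernoulli probabilities."""
    n = np.maximum(np.round(POP_SIZES * neuron_scale), 0).astype(int)
    if (n == 0).any():
        raise ValueError("neuron_scale produces an empty population")
    k_full = _k_multapse(CONN_PROB, POP_SIZES, POP_SIZES)
    p_full = k_full / np.outer(POP_SIZES, POP_SIZES)
    p_eff = p_full * (synapse_scale / neuron_scale)
    if (p_eff > 1).any():
        warnings.warn("effective connection probabilities clipped at 1")
        p_eff = np.minimum(p_eff, 1.0)
    return n, p_eff


def expected_synapse_matrix(neuron_scale: float = 1.0, synapse_scale: float = 1.0) -> np.ndarray:
    n, p_eff = effective_probabilities(neuron_scale, synapse_scale)
    return p_eff * np.outer(n, n)


def expected_total_synapses(neuron_scale: float = 1.0, synapse_scale: float = 1.0) -> float:
    return float(expected_synapse_matrix(neuron_scale, synapse_scale).sum())


def expected_mean_fanout(neuron_scale: float = 1.0, synapse_scale: float = 1.0) -> float:
    n, _ = effective_probabilities(neuron_scale, synapse_scale)
    return expected_total_synapses(neuron_scale, synapse_scale) / n.sum()


def estimate_padded_list_len(n_nodes: int, neuron_scale: float = 1.0,
                             synapse_scale: float = 1.0) -> int:
    """Analytic estimate of the common padded list length.

    The padded length is the maximum per-(source, node) synapse count over
    the whole system; with round-robin mapping the count for one source and
    one node is approximately Poisson with mean out-degree/n_nodes, and the
    maximum over all cells sits near the (1 - 1/cells) quantile.
    """
    from scipy import stats

    n, p_eff = effective_probabilities(neuron_scale, synapse_scale)
    out_deg = (p_eff * n[:, None]).sum(axis=0)  # per source population
    lam = out_deg / n_nodes
    best = 0
    for l, n_src in zip(lam, n):
        cells = max(n_src * n_nodes, 1)
        best = max(best, int(stats.poisson.ppf(1 - 1.0 / cells, l)))
    return best


def estimate_image_bytes_per_node(n_nodes: int, neuron_scale: float = 1.0,
                                  synapse_scale: float = 1.0) -> float:
    n, _ = effective_probabilities(neuron_scale, synapse_scale)
    ll = estimate_padded_list_len(n_nodes, neuron_scale, synapse_scale)
    return float(n.sum()) * ll * RECORD_BYTES


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def microcircuit_lif_params(h: float = 0.1) -> LifParams:
    return LifParams(
        tau_m=10.0, tau_syn_exc=0.5, tau_syn_inh=0.5, C_m=250.0,
        V_th=-50.0, V_reset=-65.0, E_L=-65.0, t_ref=2.0, I_dc=0.0, h=h,
    )


def microcircuit_connectivity(synapse_scale: float = 1.0,
                              neuron_scale: float = 1.0) -> ConnectivitySpec:
    _, p_eff = effective_probabilities(neuron_scale, synapse_scale)
    w = psp_to_psc(PSP_EXC_MV)
    wm = np.tile(w, (8, 8))
    wm[:, ~POP_EXC] *= G_REL_INHIBITION
    wm[0, 2] *= 2.0  # L4E -> L2/3E projection has doubled weight
    if synapse_scale < 1.0:
        wm = wm / math.sqrt(synapse_scale)
    dm = np.where(POP_EXC, DELAY_EXC_MS[0], DELAY_INH_MS[0])
    ds = np.where(POP_EXC, DELAY_EXC_MS[1], DELAY_INH_MS[1])
    return ConnectivitySpec(
        conn_prob=p_eff,
        weight_mean=wm,
        weight_sd=np.abs(wm) * W_REL_SD,
        delay_mean=dm,
        delay_sd=ds,
        delay_min=0.1,
    )


def microcircuit_dc(synapse_scale: float = 1.0) -> np.ndarray:
    """Per-population DC drive in pA: external-input mean plus, for scaled
    in-degree, compensation of the removed mean recurrent input."""
    lif = microcircuit_lif_params()
    w = psp_to_psc(PSP_EXC_MV)
    tau_s = lif.tau_syn_exc * 1e-3  # s
    dc = K_EXT * BG_RATE_HZ * tau_s * w
    if synapse_scale < 1.0:
        k_full = _k_multapse(CONN_PROB, POP_SIZES, POP_SIZES)
        k_in = k_full / POP_SIZES[:, None]  # synapses per target neuron
        wm = np.tile(w, (8, 8))
        wm[:, ~POP_EXC] *= G_REL_INHIBITION
        wm[0, 2] *= 2.0
        mean_recurrent = (k_in * wm * FULL_MEAN_RATES[None, :]).sum(axis=1) * tau_s
        dc = dc + (1.0 - math.sqrt(synapse_scale)) * mean_recurrent
    return dc


def microcircuit_dc_sd() -> np.ndarray:
    """Per-population sd (pA) of the quenched per-neuron DC spread.

    The external Poisson drive is replaced by DC; a deterministic engine has
    no noise source, so the *stationary standard deviation* of the
    Poisson-filtered current, w*sqrt(K_ext*nu_bg*tau_syn/2), is emulated as
    frozen per-neuron variability of the DC amplitude.  This sustains the
    fluctuation-driven low-rate regime that the mean alone cannot ignite.
    """
    lif = microcircuit_lif_params()
    w = psp_to_psc(PSP_EXC_MV)
    tau_s = lif.tau_syn_exc * 1e-3
    return w * np.sqrt(K_EXT * BG_RATE_HZ * tau_s / 2.0)


def generate_microcircuit(neuron_scale: float = 1.0, synapse_scale: float = 1.0,
                          seed: int = 0, h: float = 0.1) -> Network:
    """Generate a (scaled) cortical-microcircuit network.

    Deterministic given ``(neuron_scale, synapse_scale, seed)``.  Weights and
    delays are drawn normally per projection; weights are sign-constrained by
    the source population (clipped at zero), delays are clipped to
    [delay_min, ring-buffer capacity] and rounded to the timestep grid.
    """
    if not 0 < neuron_scale <= 1 or not 0 < synapse_scale <= 1:
        raise ValueError("scales must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    sizes, _ = effective_probabilities(neuron_scale, synapse_scale)
    conn = microcircuit_connectivity(synapse_scale, neuron_scale)
    dc_pop = microcircuit_dc(synapse_scale)
    lif = microcircuit_lif_params(h)

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = int(offsets[-1])
    pop_of = np.empty(n_total, dtype=np.int64)
    pops: list[PopulationSpec] = []
    for p in range(8):
        pop_of[offsets[p]:offsets[p + 1]] = p
        pops.append(PopulationSpec(
            name=POP_NAMES[p], size=int(sizes[p]), is_excitatory=bool(POP_EXC[p]),
            lif=lif, dc_amplitude=float(dc_pop[p]),
        ))

    # one slot of headroom below the buffer depth keeps asynchronous writes
    # from skewed neighbor nodes out of the slot currently being consumed
    max_delay_ms = {True: (EXC_DEPTH - 1) * h, False: (INH_DEPTH - 1) * h}
    src_all, tgt_all, dly_all, w_all = [], [], [], []
    for j in range(8):  # source population
        n_src = int(sizes[j])
        exc = bool(POP_EXC[j])
        dmean, dsd = conn.delay_mean[j], conn.delay_sd[j]
        for i in range(8):  # target population
            p = conn.conn_prob[i, j]
            if p == 0.0:
                continue
            n_tgt = int(sizes[i])
            counts = rng.binomial(n_tgt, p, size=n_src)
            total = int(counts.sum())
            if total == 0:
                continue
            src = np.repeat(np.arange(n_src), counts) + offsets[j]
            tgt = np.empty(total, dtype=np.int64)
            pos = 0
            for k in counts:
                if k:
                    tgt[pos:pos + k] = rng.choice(n_tgt, size=k, replace=False)
                    pos += k
            tgt += offsets[i]
            w = rng.normal(conn.weight_mean[i, j], conn.weight_sd[i, j], size=total)
            w = np.maximum(w, 0.0) if exc else np.minimum(w, 0.0)
            d = rng.normal(dmean, dsd, size=total)
            d = np.clip(d, conn.delay_min, max_delay_ms[exc])
            steps = np.maximum(np.round(d / h), 1).astype(np.int64)
            src_all.append(src)
            tgt_all.append(tgt)
            dly_all.append(steps)
            w_all.append(w)

    if src_all:
        src = np.concatenate(src_all)
        order = np.argsort(src, kind="stable")
        src = src[order]
        tgt = np.concatenate(tgt_all)[order]
        dly = np.concatenate(dly_all)[order]
        w = np.concatenate(w_all)[order]
        raw = np.round(w / DEFAULT_WEIGHT_SCALE).astype(np.int64)
        if np.abs(raw).max() >= 2 ** 31:
            raise OverflowError("synaptic weight outside fixed-point range")
        indptr = np.zeros(n_total + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        connectome = Connectome(
            indptr=indptr,
            targets=tgt,
            delay_steps=dly.astype(np.uint8),
            weight_raw=raw.astype(np.int32),
            is_exc_source=POP_EXC[pop_of],
        )
    else:
        connectome = Connectome(
            indptr=np.zeros(n_total + 1, dtype=np.int64),
            targets=np.empty(0, dtype=np.int64),
            delay_steps=np.empty(0, dtype=np.uint8),
            weight_raw=np.empty(0, dtype=np.int32),
            is_exc_source=POP_EXC[pop_of],
        )

    v_init = rng.normal(V_INIT_MEAN_MV, V_INIT_SD_MV, size=n_total)
    dc = rng.normal(dc_pop[pop_of], microcircuit_dc_sd()[pop_of])
    return Network(
        populations=pops,
        pop_of=pop_of,
        v_init=v_init,
        dc=dc,
        connectome=connectome,
        h=h,
    )


# ---------------------------------------------------------------------------
# node mapping and padded memory image
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mapping:
    """Round-robin neuron-to-node assignment (neuron g lives on node g mod N)."""

    node_of: np.ndarray
    local_index: np.ndarray
    n_nodes: int

    def loads(self) -> np.ndarray:
        return np.bincount(self.node_of, minlength=self.n_nodes)

    def globals_of(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.node_of == node)


def map_round_robin(n_neurons: int, n_nodes: int) -> Mapping:
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    g = np.arange(n_neurons)
    local = g // n_nodes
    if n_neurons and local.max() >= 2 ** 16:
        raise OverflowError("node-local index exceeds 16 bits")
    return Mapping(node_of=g % n_nodes, local_index=local, n_nodes=n_nodes)


@dataclass(frozen=True)
class SynapseRecord:
    target_id: int   # node-local, 16 bit
    delay: int       # timesteps, 8 bit, >= 1 for real synapses
    weight_raw: int  # 32-bit fixed point

    @property
    def is_padding(self) -> bool:
        return self.target_id == PADDING_TARGET


PADDING_RECORD = SynapseRecord(PADDING_TARGET, 0, 0)


def encode_record(r: SynapseRecord) -> bytes:
    """Little-endian 8-byte layout: u16 target, u8 delay, 1 zero pad, i32 weight."""
    return struct.pack("<HBBi", r.target_id, r.delay, 0, r.weight_raw)


def decode_record(b: bytes) -> SynapseRecord:
    if len(b) != RECORD_BYTES:
        raise ValueError(f"synapse record must be {RECORD_BYTES} bytes, got {len(b)}")
    target, delay, _pad, weight = struct.unpack("<HBBi", b)
    return SynapseRecord(target, delay, weight)


@dataclass
class PaddedListImage:
    """Per-node connectome memory image: one padded list per global source.

    The list of source ``s`` occupies bytes ``[s*list_len*8, (s+1)*list_len*8)``
    — address computation needs no table.  Arrays are (n_sources, list_len);
    padding entries carry ``target == PADDING_TARGET`` and zero weight.
    """

    n_sources: int
    list_len: int
    target: np.ndarray  # uint16
    delay: np.ndarray   # uint8
    weight: np.ndarray  # int32
    weight_scale: float = DEFAULT_WEIGHT_SCALE

    @property
    def nbytes(self) -> int:
        return self.n_sources * self.list_len * RECORD_BYTES

    def byte_offset(self, source_id: int) -> int:
        return source_id * self.list_len * RECORD_BYTES

    def to_bytes(self) -> bytes:
        rec = np.zeros((self.n_sources, self.list_len),
                       dtype=[("t", "<u2"), ("d", "u1"), ("p", "u1"), ("w", "<i4")])
        rec["t"] = self.target
        rec["d"] = self.delay
        rec["w"] = self.weight
        return rec.tobytes()


def build_padded_images(connectome: Connectome, mapping: Mapping) -> list[PaddedListImage]:
    """Split a connectome into per-node padded-list images (broadcast layout).

    Node k's image is keyed by *global* source id and holds only synapses
    whose targets live on node k, with 16-bit node-local target indices.
    ``list_len`` is the global maximum per-(source, node) count, shared by
    all nodes so address arithmetic is uniform across the system.
    """
    n = connectome.n_neurons
    if mapping.local_index.size and mapping.local_index.max() >= PADDING_TARGET:
        raise OverflowError("node-local index collides with the padding marker")
    counts = np.zeros((n, mapping.n_nodes), dtype=np.int64)
    src = np.repeat(np.arange(n), connectome.out_degree())
    tgt_node = mapping.node_of[connectome.targets] if connectome.n_synapses else np.empty(0, np.int64)
    if connectome.n_synapses:
        np.add.at(counts, (src, tgt_node), 1)
    list_len = int(counts.max()) if connectome.n_synapses else 0

    images = []
    for k in range(mapping.n_nodes):
        img = PaddedListImage(
            n_sources=n, list_len=list_len,
            target=np.full((n, list_len), PADDING_TARGET, dtype=np.uint16),
            delay=np.zeros((n, list_len), dtype=np.uint8),
            weight=np.zeros((n, list_len), dtype=np.int32),
        )
        if connectome.n_synapses:
            sel = np.flatnonzero(tgt_node == k)
            s = src[sel]
            # stable positions within each source's list
            order = np.argsort(s, kind="stable")
            sel, s = sel[order], s[order]
            pos = np.arange(len(s)) - np.concatenate(
                [[0], np.cumsum(np.bincount(s, minlength=n))])[s]
            img.target[s, pos] = mapping.local_index[connectome.targets[sel]]
            img.delay[s, pos] = connectome.delay_steps[sel]
            img.weight[s, pos] = connectome.weight_raw[sel]
        images.append(img)
    return images


def lookup(source_id: int, image: PaddedListImage):
    """Non-padding records of one source plus the bytes the memory model charges.

    The full padded list is always read: ``bytes_read = list_len * 8``.
    """
    if not 0 <= source_id < image.n_sources:
        raise KeyError(f"unknown source {source_id}")
    t = image.target[source_id]
    real = t != PADDING_TARGET
    records = [
        SynapseRecord(int(t[i]), int(image.delay[source_id, i]),
                      int(image.weight[source_id, i]))
        for i in np.flatnonzero(real)
    ]
    return records, image.list_len * RECORD_BYTES
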