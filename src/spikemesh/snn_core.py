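"""Leaky integrate-and-fire neurons with exponential-current synapses.

The neuron model is the standard LIF point neuron with current-based (CUBA)
synapses: the membrane potential decays exponentially toward the resting
potential ``E_L`` with time constant ``tau_m`` while excitatory and inhibitory
synaptic currents decay with their own time constants and are injected
impulsively by incoming spikes.  Because the subthreshold dynamics are linear,
the per-timestep update is computed in closed form ("exact exponential
integration"): a small propagator matrix maps the state at step ``t`` to the
state at ``t+1`` without numerical ODE error.

Two arithmetic modes are supported throughout:

``fixed``
    Hardware-faithful mode: membrane/current state in IEEE single precision,
    synaptic accumulation in 32-bit fixed point (Q16.16, pA) ring buffers.
``double``
    Reference mode: state arithmetic in double precision.  Ring-buffer
    accumulation still sums the integer fixed-point weights (integer sums are
    exact and order-independent, so both modes are bit-deterministic).

Closed-form propagators, with ``h`` the timestep and ``V`` measured relative
to ``E_L``::

    p_vv = exp(-h/tau_m)
    p_ss = exp(-h/tau_syn)                          (one per synapse sign)
    p_vs = tau_m*tau_syn / (C_m*(tau_syn - tau_m)) * (p_ss - p_vv)
    p_dc = tau_m/C_m * (1 - p_vv)

and in the degenerate limit ``tau_syn == tau_m``::

    p_vs = h/C_m * exp(-h/tau_m)

Update order per step (matching common reference simulators): the membrane
integrates the *previous* step's synaptic currents, then the currents decay
and absorb the ring-buffer input of the current step.  Refractoriness is
counted in timesteps, decrement-first: a neuron that spiked at step ``t``
with ``t_ref = k*h`` resumes integration at step ``t+k`` (so ``t_ref = h``
permits firing on every timestep).  Threshold comparison is closed
(``v >= V_th``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "LifParams",
    "Propagators",
    "NeuronState",
    "RingBuffer",
    "FixedPointWeight",
    "DEFAULT_WEIGHT_SCALE",
    "EXC_DEPTH",
    "INH_DEPTH",
    "compute_propagators",
    "step_neuron",
    "accumulate_spike",
    "advance_ring",
    "encode_weight",
    "decode_weight",
    "StepKernel",
    "run_network",
]

#: ring-buffer depths in timesteps, set by the maximum synaptic delays of the
#: cortical microcircuit at h = 0.1 ms (6.4 ms excitatory, 3.2 ms inhibitory)
EXC_DEPTH = 64
INH_DEPTH = 32

#: Q16.16 fixed-point weight resolution in pA per LSB (range +-32768 pA)
DEFAULT_WEIGHT_SCALE = 2.0 ** -16

_I32_MIN = -(2 ** 31)
_I32_MAX = 2 ** 31 - 1


class InvalidParameterError(ValueError):
    """A neuron parameter violates its invariants."""


class DelayOverflowError(ValueError):
    """A synaptic delay exceeds the ring-buffer depth."""


class AccumulatorOverflowError(OverflowError):
    """A ring-buffer slot left the signed 32-bit accumulator range."""


@dataclass(frozen=True)
class LifParams:
    """Constants of one LIF/CUBA neuron.

    Units: time constants and ``h`` in ms, capacitance in pF, potentials in
    mV, currents in pA.  Defaults are the cortical-microcircuit values.
    """

    tau_m: float = 10.0
    tau_syn_exc: float = 0.5
    tau_syn_inh: float = 0.5
    C_m: float = 250.0
    V_th: float = -50.0
    V_reset: float = -65.0
    E_L: float = -65.0
    t_ref: float = 2.0
    I_dc: float = 0.0
    h: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_syn_exc <= 0 or self.tau_syn_inh <= 0:
            raise InvalidParameterError("time constants must be positive")
        if self.C_m <= 0:
            raise InvalidParameterError("C_m must be positive")
        if self.h <= 0:
            raise InvalidParameterError("h must be positive")
        if self.V_reset >= self.V_th:
            raise InvalidParameterError("V_reset must lie below V_th")
        if self.t_ref < 0:
            raise InvalidParameterError("t_ref must be non-negative")

    @property
    def refractory_steps(self) -> int:
        return int(round(self.t_ref / self.h))


@dataclass(frozen=True)
class Propagators:
    """Closed-form per-step update coefficients (pure function of LifParams)."""

    p_vv: float
    p_ee: float
    p_ii: float
    p_ve: float  # mV per pA of excitatory current
    p_vi: float  # mV per pA of inhibitory current
    p_dc: float  # mV per pA of DC drive


def _coupling(tau_m: float, tau_syn: float, c_m: float, h: float) -> float:
    if tau_syn == tau_m:
        return h / c_m * math.exp(-h / tau_m)
    return (
        tau_m * tau_syn / (c_m * (tau_syn - tau_m))
        * (math.exp(-h / tau_syn) - math.exp(-h / tau_m))
    )


def compute_propagators(params: LifParams) -> Propagators:
    """Exact-integration propagators for one timestep of length ``params.h``."""
    h, tau_m, c_m = params.h, params.tau_m, params.C_m
    p_vv = math.exp(-h / tau_m)
    return Propagators(
        p_vv=p_vv,
        p_ee=math.exp(-h / params.tau_syn_exc),
        p_ii=math.exp(-h / params.tau_syn_inh),
        p_ve=_coupling(tau_m, params.tau_syn_exc, c_m, h),
        p_vi=_coupling(tau_m, params.tau_syn_inh, c_m, h),
        p_dc=tau_m / c_m * (1.0 - p_vv),
    )


@dataclass
class NeuronState:
    """Dynamic state of a single neuron."""

    v_m: float
    i_exc: float = 0.0
    i_inh: float = 0.0
    refr_steps: int = 0


def step_neuron(
    state: NeuronState,
    prop: Propagators,
    params: LifParams,
    exc_in: float,
    inh_in: float,
    mode: str = "double",
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one timestep.

    ``exc_in``/``inh_in`` are the lumped ring-buffer outputs (pA) for the
    current step.  Returns the new state and whether the neuron spiked.
    In ``fixed`` mode every membrane/current operation is rounded to single
    precision, mirroring the hardware datapath.
    """
    dt = np.float32 if mode == "fixed" else float
    v, ie, ii, refr = state.v_m, state.i_exc, state.i_inh, state.refr_steps
    spiked = False
    if refr > 0:
        refr -= 1
    if refr == 0:
        v = dt(
            dt(params.E_L)
            + dt(dt(prop.p_vv) * dt(v - params.E_L))
            + dt(dt(prop.p_ve) * dt(ie))
            + dt(dt(prop.p_vi) * dt(ii))
            + dt(dt(prop.p_dc) * dt(params.I_dc))
        )
    else:
        v = params.V_reset
    ie = dt(dt(dt(prop.p_ee) * dt(ie)) + dt(exc_in))
    ii = dt(dt(dt(prop.p_ii) * dt(ii)) + dt(inh_in))
    if refr == 0 and v >= params.V_th:
        spiked = True
        v = params.V_reset
        refr = params.refractory_steps
    return NeuronState(float(v), float(ie), float(ii), refr), spiked


# ---------------------------------------------------------------------------
# fixed-point weights
# ---------------------------------------------------------------------------

def encode_weight(pa: float, scale: float = DEFAULT_WEIGHT_SCALE) -> int:
    """Quantize a weight in pA to the signed 32-bit fixed-point raw value."""
    raw = int(round(pa / scale))
    if not _I32_MIN <= raw <= _I32_MAX:
        raise AccumulatorOverflowError(f"weight {pa} pA outside fixed-point range")
    return raw


def decode_weight(raw: int, scale: float = DEFAULT_WEIGHT_SCALE) -> float:
    return raw * scale


@dataclass(frozen=True)
class FixedPointWeight:
    """A synaptic weight as stored in the connectome: raw Q16.16 integer."""

    raw: int
    scale: float = DEFAULT_WEIGHT_SCALE

    def __post_init__(self) -> None:
        if not _I32_MIN <= self.raw <= _I32_MAX:
            raise AccumulatorOverflowError("raw weight outside int32 range")

    @classmethod
    def from_pa(cls, pa: float, scale: float = DEFAULT_WEIGHT_SCALE) -> "FixedPointWeight":
        return cls(encode_weight(pa, scale), scale)

    @property
    def pa(self) -> float:
        return decode_weight(self.raw, self.scale)


# ---------------------------------------------------------------------------
# ring buffer (per-neuron scalar reference; the network engine vectorizes it)
# ---------------------------------------------------------------------------

@dataclass
class RingBuffer:
    """Per-neuron future-input accumulators, one slot per timestep of delay.

    Accumulation is exact integer addition of raw fixed-point weights, hence
    order-independent; a slot is zeroed immediately after it is read.
    """

    scale: float = DEFAULT_WEIGHT_SCALE
    exc_slots: np.ndarray = field(default_factory=lambda: np.zeros(EXC_DEPTH, dtype=np.int64))
    inh_slots: np.ndarray = field(default_factory=lambda: np.zeros(INH_DEPTH, dtype=np.int64))
    read_index: int = 0


def accumulate_spike(rb: RingBuffer, delay_steps: int, w: FixedPointWeight, is_excitatory: bool) -> None:
    """Add a spike's raw weight into the slot ``delay_steps`` ahead of the read pointer."""
    slots = rb.exc_slots if is_excitatory else rb.inh_slots
    depth = len(slots)
    if not 1 <= delay_steps <= depth:
        raise DelayOverflowError(
            f"delay {delay_steps} outside 1..{depth} for "
            f"{'excitatory' if is_excitatory else 'inhibitory'} input"
        )
    idx = (rb.read_index + delay_steps) % depth
    total = int(slots[idx]) + w.raw
    if not _I32_MIN <= total <= _I32_MAX:
        raise AccumulatorOverflowError("ring-buffer slot overflow")
    slots[idx] = total


def advance_ring(rb: RingBuffer) -> tuple[float, float]:
    """Advance the pointer, read and zero the new slots; returns pA values.

    The pointer moves first, so a spike accumulated with delay ``d`` is
    returned by the ``d``-th subsequent advance (the next timestep is the
    first future slot).
    """
    rb.read_index += 1
    i_e = rb.read_index % EXC_DEPTH
    i_i = rb.read_index % INH_DEPTH
    exc = decode_weight(int(rb.exc_slots[i_e]), rb.scale)
    inh = decode_weight(int(rb.inh_slots[i_i]), rb.scale)
    rb.exc_slots[i_e] = 0
    rb.inh_slots[i_i] = 0
    return exc, inh


# ---------------------------------------------------------------------------
# vectorized network engine
# ---------------------------------------------------------------------------

class StepKernel:
    """Vectorized one-step update for a group of neurons.

    Holds per-neuron coefficient arrays in the dtype of the chosen mode.  The
    same kernel instance is used by the standalone engine and by each node of
    the virtual prototype, which guarantees bit-identical dynamics regardless
    of how neurons are partitioned.
    """

    def __init__(self, network, idx: np.ndarray, mode: str = "fixed"):
        if mode not in ("fixed", "double"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.dtype = np.float32 if mode == "fixed" else np.float64
        dt = self.dtype
        pops = network.populations
        pop_of = network.pop_of[idx]
        n = len(idx)

        props = [compute_propagators(p.lif) for p in pops]
        self.p_vv = np.empty(n, dt)
        self.p_ee = np.empty(n, dt)
        self.p_ii = np.empty(n, dt)
        self.p_ve = np.empty(n, dt)
        self.p_vi = np.empty(n, dt)
        self.dc_term = np.empty(n, dt)  # p_dc * I_dc, mV
        self.e_l = np.empty(n, dt)
        self.v_th = np.empty(n, dt)
        self.v_reset = np.empty(n, dt)
        self.refr_reset = np.empty(n, np.int32)
        dc = network.dc[idx]
        for p, (spec, pr) in enumerate(zip(pops, props)):
            m = pop_of == p
            self.p_vv[m] = pr.p_vv
            self.p_ee[m] = pr.p_ee
            self.p_ii[m] = pr.p_ii
            self.p_ve[m] = pr.p_ve
            self.p_vi[m] = pr.p_vi
            self.dc_term[m] = (pr.p_dc * dc[m]).astype(dt)
            self.e_l[m] = spec.lif.E_L
            self.v_th[m] = spec.lif.V_th
            self.v_reset[m] = spec.lif.V_reset
            self.refr_reset[m] = spec.lif.refractory_steps

        self.v = network.v_init[idx].astype(dt).copy()
        self.i_exc = np.zeros(n, dt)
        self.i_inh = np.zeros(n, dt)
        self.refr = np.zeros(n, np.int32)
        # initial states above threshold fire on the first step
        self.scale = dt(network.weight_scale)

    def step(self, exc_raw: np.ndarray, inh_raw: np.ndarray) -> np.ndarray:
        """One timestep; raw integer ring-buffer slots in, spiking indices out."""
        dt = self.dtype
        in_e = exc_raw.astype(dt) * self.scale
        in_i = inh_raw.astype(dt) * self.scale
        np.maximum(self.refr - 1, 0, out=self.refr)
        active = self.refr == 0
        v_new = (
            self.e_l
            + self.p_vv * (self.v - self.e_l)
            + self.p_ve * self.i_exc
            + self.p_vi * self.i_inh
            + self.dc_term
        )
        self.v = np.where(active, v_new, self.v_reset)
        self.i_exc = self.p_ee * self.i_exc + in_e
        self.i_inh = self.p_ii * self.i_inh + in_i
        spiked = active & (self.v >= self.v_th)
        self.v[spiked] = self.v_reset[spiked]
        self.refr[spiked] = self.refr_reset[spiked]
        return np.flatnonzero(spiked)


def _check_slots(slots: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    touched = slots[rows, cols]
    if touched.size and (touched.max() > _I32_MAX or touched.min() < _I32_MIN):
        raise AccumulatorOverflowError("ring-buffer slot overflow")


def run_network(network, n_steps: int, mode: str = "fixed", record_potentials=None):
    """Simulate a whole network for ``n_steps`` timesteps.

    Returns a :class:`spikemesh.analysis.SpikeRaster`.  ``record_potentials``
    may be a sequence of neuron ids whose membrane traces are returned as a
    second value (shape ``(n_steps, len(ids))``).
    """
    from .analysis import SpikeRaster

    n = network.n_neurons
    kern = StepKernel(network, np.arange(n), mode=mode)
    buf_e = np.zeros((EXC_DEPTH, n), dtype=np.int64)
    buf_i = np.zeros((INH_DEPTH, n), dtype=np.int64)
    conn = network.connectome
    ev_neuron: list[np.ndarray] = []
    ev_step: list[np.ndarray] = []
    traces = None
    if record_potentials is not None:
        record_potentials = np.asarray(record_potentials, dtype=np.int64)
        traces = np.zeros((n_steps, len(record_potentials)))

    for t in range(n_steps):
        se, si = t % EXC_DEPTH, t % INH_DEPTH
        spikes = kern.step(buf_e[se], buf_i[si])
        buf_e[se] = 0
        buf_i[si] = 0
        if traces is not None:
            traces[t] = kern.v[record_potentials]
        if spikes.size:
            ev_neuron.append(spikes.astype(np.int64))
            ev_step.append(np.full(spikes.size, t, dtype=np.int64))
            if conn is not None and conn.n_synapses:
                tgt, dly, raw, exc_mask = conn.outgoing(spikes)
                if tgt.size:
                    te, de = tgt[exc_mask], dly[exc_mask]
                    rows = (t + de) % EXC_DEPTH
                    np.add.at(buf_e, (rows, te), raw[exc_mask])
                    _check_slots(buf_e, rows, te)
                    ti, di = tgt[~exc_mask], dly[~exc_mask]
                    rows = (t + di) % INH_DEPTH
                    np.add.at(buf_i, (rows, ti), raw[~exc_mask])
                    _check_slots(buf_i, rows, ti)

    if ev_neuron:
        neuron = np.concatenate(ev_neuron)
        step = np.concatenate(ev_step)
    else:
        neuron = np.empty(0, dtype=np.int64)
        step = np.empty(0, dtype=np.int64)
    raster = SpikeRaster(
        neuron=neuron, step=step, n_neurons=n, n_steps=n_steps, h=network.h
    )
    if traces is not None:
        return raster, traces
    return raster
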