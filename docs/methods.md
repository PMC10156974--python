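# Methods

This note documents the models implemented in `spikemesh`, the conventions
and defaults they use, and what the package's tests do and do not establish.

## Neuron model and exact integration

Neurons are leaky integrate-and-fire points with current-based synapses:

    dV/dt = -(V - E_L)/τ_m + (I_e + I_i + I_dc)/C_m
    dI_s/dt = -I_s/τ_s                     (s ∈ {e, i})

Because the subthreshold system is linear, the per-timestep update is the
exact matrix exponential evaluated once per parameter set ("exact
exponential integration"); no ODE-solver error is incurred at any `h`.
With `V` measured relative to `E_L`:

    p_vv = exp(-h/τ_m)          p_ss = exp(-h/τ_s)
    p_vs = τ_m τ_s / (C_m (τ_s - τ_m)) · (p_ss - p_vv)
    p_dc = τ_m/C_m · (1 - p_vv)

and in the degenerate limit `τ_s = τ_m`: `p_vs = (h/C_m)·exp(-h/τ_m)` (the
analytic limit of the general form; the code branches on exact equality and
the tests verify continuity against `τ_s = τ_m(1 ± 10⁻⁶)`).

Update order per step: (1) membrane integrates the *previous* step's
synaptic currents, (2) currents decay and absorb the current step's
ring-buffer input, (3) threshold test.  Conventions:

- Threshold comparison is closed (`V ≥ V_th`); ties spike.
- The spike is recorded at the step in which the threshold is crossed;
  synaptic delay is counted from that step.
- Refractoriness is decrement-first: a neuron spiking at step `t` with
  `t_ref = k·h` holds `V = V_reset` for steps `t+1 … t+k-1` and resumes
  integration (and may fire) at step `t+k`.  Consequently `t_ref = h`
  permits firing on every timestep — the construction used by the
  always-spiking calibration networks, which demand one action potential
  per step.  (A reference simulator that updates before decrementing would
  fire at most every second step with a one-step refractory period.)

### Arithmetic modes

`fixed` mode mirrors the hardware datapath: membrane and current state in
IEEE single precision, synaptic accumulation as exact integer addition of
Q16.16 fixed-point weights (2⁻¹⁶ pA per LSB, range ±32,768 pA — microcircuit
weights are of order 10²–10³ pA).  `double` mode is the reference: state
arithmetic in double precision.  Both modes accumulate ring-buffer input as
integers, so accumulation is order-independent and bit-deterministic in
either mode; only the state arithmetic differs.  Accumulator overflow
beyond signed 32 bits raises an error rather than wrapping.

Ring buffers hold 64 excitatory and 32 inhibitory future-timestep slots
(6.4/3.2 ms at `h = 0.1 ms`), fixed by the maximum synaptic delays of the
microcircuit.  A slot is zeroed immediately after it is read.

## Microcircuit generator

The generator emulates the full-density cortical microcircuit: eight
populations (L2/3E … L6I, 77,169 neurons at full scale) with the published
connection-probability table, normal weight and delay distributions
(excitatory 1.5 ± 0.75 ms, inhibitory 0.75 ± 0.375 ms, minimum one step),
weights sign-constrained per source population (inhibitory = −4× excitatory,
L4E→L2/3E doubled), and external drive emulated as DC current.

Drawing model: synapses are pairwise Bernoulli.  The published reference
model draws a *fixed total number* `K(p) = ln(1-p)/ln(1-1/(N_s N_t))` per
projection; we use effective pairwise probabilities `p_eff = K/(N_s N_t)` so
expected projection sizes match it — expected mean fanout 3,873 against the
published ≈3,880, expected total ≈2.99·10⁸ synapses (2.1 GB at the 56-bit
logical record, 2.4 GB stored at 8 B/synapse).

Scaling: `neuron_scale` multiplies population sizes; `synapse_scale`
multiplies the expected in-degree.  When in-degree is reduced, weights are
scaled by `1/√synapse_scale` (preserving input variance conditional on
rates) and the removed mean recurrent input, evaluated at the published
full-scale population rates, is added back as DC — the established
downscaling recipe for this model.

External drive: the Poisson input of the reference model is replaced by its
DC mean `I_dc = K_ext · ν_bg · τ_syn · w` (≈351 pA per 1,000 external
connections at 8 Hz).  A deterministic engine has no noise source, so the
*stationary standard deviation* of the Poisson-filtered current,
`σ = w·√(K_ext · ν_bg · τ_syn / 2)`, is rendered as quenched per-neuron
variability of the DC amplitude.  Without it a scaled network cannot ignite
or sustain activity (the mean operating point is subthreshold); with it, the
2%-scale network settles into asynchronous firing at population rates of
roughly 4–20 Hz with near-zero mean pairwise correlation.  This emulation
reproduces the *distributional* character of the drive, not its temporal
statistics: per-neuron rates are broader, and interval irregularity lower,
than in a temporally-noisy reference — which is why validation compares
arithmetic variants of the *same* model rather than absolute biology.

Generated delays are quantized to the step grid and capped at depth−1 slots
(63/31): a delay equal to the full buffer depth would let an asynchronous
write from a one-step-skewed neighbor collide with the slot currently being
consumed.  Truncation probability under the delay distributions is ~5·10⁻¹¹.

## Memory layout and mapping

Neurons are assigned to nodes round-robin (`node = id mod N`, dense local
indices).  For broadcast operation every node stores, for *every* global
source, the list of that source's synapses whose targets are local, padded
to one global common length: the DRAM address of any list is then
`source_id × list_len × 8 B` with no lookup table.  Each record is 8 bytes:
16-bit local target, 8-bit delay, one alignment pad byte, 32-bit fixed-point
weight (little-endian); `target = 0xFFFF` marks padding.  At full scale on
35 nodes the analytic estimate of the padded image (maximum per-source,
per-node count via the binomial tail) is ~150 MB per node.

## Interconnect and static estimator

Nodes form a `width × height` grid; every node links directly to all nodes
in its row (6.25 Gbps) and column (6.0 Gbps), so broadcast completes in two
stages: stage 1 to the source's row and column, stage 2 forwarded by the
stage-1 recipients in the source's column along their own rows.  Delivery
is exactly-once with a worst case of two hops (verified exhaustively for
all grids up to 6×6).

The static estimator prices this in expectation, with no queueing or
sampling: each node injects `neurons × rate × acceleration` messages per
wall-clock second, each 128 bits, delivered once to every other node.  For
the full microcircuit on 7×5 (mean biological rate derived from the
222,545,972 spikes of a 900 s run, acceleration 20.36) the maximum per-node
ingress is 0.63 Gbps — below the 1 Gbps planning threshold for the links.

## Virtual prototype

The event-driven model treats messages and memory requests as atomic events
with start/finish times; there is no cycle-level modeling beyond the worker
formula.  Per node and timestep:

- **Compute**: `(NpW + pipeline_depth)/f_clk + step_overhead`, workers in
  parallel (the slowest worker gates the node).  The overhead default
  (591.3 ns) absorbs scheduling/local-sync costs so that a silent
  single-node step at NpW = 1 lasts 755 ns with default parameters.
- **Spike pipeline**: the local router admits one spike per
  `spike_local_cost` (43.5 ns default, serial), then issues a DRAM read of
  the full padded list.  One request occupies one of two channels; a lone
  request transfers at the full `BW_max` (10 GB/s), concurrent requests
  share it.  Streaming into ring buffers is cut-through, so the transfer is
  additionally capped by (distinct target buffers × 1.5 GB/s) — a single
  self-targeting ("autapse") list converges to 1.5 GB/s, evenly-spread long
  lists with parallel requests reach ≥90% of `BW_max`.  A zero-length list
  issues no request.
- **Links**: arrival = departure + per-axis latency (794 ns row, 815 ns
  column — the measured one-way latency of one 128-bit packet, including
  its own serialization); link bandwidth (×64/66 line-code efficiency) only
  gates back-to-back departures.  Links are lossless FIFOs; the reliability
  layer of a real transceiver is assumed folded into the measured latency.
- **Synchronization**: after computing step `t` a node sends a phase-1 sync
  on every link, ordered after its last spike there; phase-2 is emitted
  once phase-1 has arrived from all neighbors.  A node starts step `t+1`
  when the final-phase syncs of `t` have arrived and its lookup pipeline
  has drained.  `sync_count` defaults to the worst-case hop count (2 on a
  2-D grid, 1 on a line, 0 alone).  With fewer syncs than hops, a spike
  whose ring-buffer slot has already been consumed is dropped and counted
  in a late-spike error register — never silently applied — so correctness
  violations are observable, mirroring the speed-versus-safety trade-off of
  the modeled hardware.
- **Determinism**: simultaneous events are ordered by (time, kind priority
  sync > spike > compute, node id, sequence number); all randomness derives
  from the run seed (statistical-mode draws use per-(node, step) seed
  streams).  An event-count watchdog guards against runaway workloads.

Functional mode executes the same vectorized kernel as the standalone
engine on each node's neuron subset; integer ring-buffer accumulation makes
the result independent of delivery order, so spike trains are bit-identical
to the engine for any performance parameters (asserted over randomized
parameter draws).  Statistical mode draws binomial per-step spike counts at
a configured biological rate and charges a configured lookup size.

Wall-clock time τ is the completion time of the last node's last step;
acceleration is `a = n·h/τ`.

## Calibration experiments

Each experiment isolates one component and its extraction is a difference
formula, so constant offsets cancel:

- **Silent nets** (resting potential, no drive, no synapses): per-step
  duration is affine in NpW; the slope over {1, 255} recovers
  `τ_neuron = 1/f_clk` (5.28 ns) exactly; the 1×1/2×1/1×2 differences
  recover the row/column link latencies exactly.
- **Autospike nets** (`t_ref = h`, saturating 50,000 pA DC — threshold
  crossing from reset needs ≈38,000 pA — fanout 0): per-additional-spike
  duration recovers the serial router cost.
- **Memory sweeps** (always-spiking sources, controlled list length, even
  or autapse targeting): the access time of a 1,000-synapse list, isolated
  by subtracting a compute-matched silent baseline and the router slot,
  gives a mean bandwidth of 5 GB/s; `t_lat = n_bytes(1/BW_mean − 1/BW_max)`
  then recovers the injected 800 ns exactly.  The 800 ns default is itself
  an *effective* calibration value — in a physical system it absorbs
  spike-generation and lookup overheads beyond the raw DRAM latency.

The parameter-recovery property (all recoveries within 2%) is the module's
acceptance surface and runs on grids ≤ 2 nodes and ≤ 255 neurons/worker
with 50–200-step measurements — sizes chosen because the silent/autospike
workloads reach steady state within a handful of steps.

## Validation statistics

Spike-train comparison across arithmetic variants of a chaotic network is
meaningful only at the distribution level.  `compute_stats` reports, after
discarding the first 10,000 steps (1 s biological): per-neuron time-averaged
rates; CV of inter-spike intervals (reported as missing, not zero, below
two spikes); and Pearson correlations of 2-ms-binned trains for a
seed-deterministic sample of 200 neurons.

`corridor_compare` judges a run against reference runs per population: the
run is *inside* the corridor when its per-neuron distribution is at least
as close (two-sample Kolmogorov–Smirnov distance) to some reference as the
references are to each other — i.e. arithmetic-induced deviation does not
exceed seed-induced deviation.  A strict per-bin histogram envelope from a
handful of reference seeds would be noise-dominated (an equivalent sample
falls outside a 3-sample min–max per bin with probability ½); the KS form
preserves the envelope's intent at finite sample size.  Measured at 2%
scale over 10 s biological: fixed-vs-double KS distances 0.01–0.05 against
seed spreads 0.09–0.38, and total spike counts within 0.4%.

Scalar metrics: spike-count deviation `100·|S_t − S_r|/S_r` (two decimals),
energy per synaptic event `P·Δt/(S·f_o)` in nJ, acceleration `n·h/τ`.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each property is meaningfully
exercised: microcircuit fixtures at 0.13–3% scale (100–2,300 neurons);
functional virtual-prototype runs of ≤ 2,000 steps on ≤ 2×2 grids;
statistical workloads of 40–600 steps on grids up to 7×5; the corridor
validation at 2% scale (1,543 neurons) over 100,000 steps in four runs.
Full-scale quantities (fanout, memory footprints, bandwidth) are computed
from expected-value arithmetic rather than instantiated connectomes.

## Known limitations

- The memory model has no banks, refresh, or reordering; request transfer
  rates are fixed at issue time from instantaneous channel occupancy.  The
  non-monotone bandwidth anomaly real hardware shows for many parallel
  autapse-style accesses at intermediate list lengths is not reproduced.
- FIFO capacities in front of ring buffers are not modeled explicitly;
  back-pressure enters only through the streaming bandwidth cap.
- Full-scale virtual-prototype acceleration is more pessimistic than the
  modeled hardware class achieves, mainly because per-request memory
  latency is serialized per channel rather than pipelined across in-flight
  requests.  Ordinal scaling behavior (single node fastest at the smallest
  scale, clusters overtaking as the problem grows, sub-linear decay) is
  reproduced.
- The quenched-DC emulation of external drive reproduces distributional,
  not temporal, input statistics; CV-of-ISI distributions are therefore not
  comparable to a temporally-noisy reference, and validation is restricted
  to comparisons between arithmetic variants of the same model.
- Unicast casting and long-hop topologies are out of validated scope.
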