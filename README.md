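# spikemesh

Spiking-network simulation coupled to a performance model of an
FPGA-cluster-style neuromorphic accelerator.

`spikemesh` is aimed at computational neuroscientists and hardware architects
who want to ask, *before* building anything: how fast would a cluster of
simple time-driven compute nodes on a row/column-connected mesh simulate a
cortical network, and would the result still be correct? The package couples
three layers that are normally separate tools:

1. **A functional engine** for leaky integrate-and-fire (LIF) neurons with
   exponential-current (CUBA) synapses, integrated exactly per timestep
   (`V(t+h) = e^{-h/τ_m} V(t) + p_{ve} I_e(t) + p_{vi} I_i(t) + p_{dc} I_{dc}`,
   the propagator-matrix update for linear dynamics), with hardware-faithful
   data paths: 32-bit fixed-point (Q16.16) weight accumulation in per-neuron
   ring buffers (64 excitatory / 32 inhibitory delay slots) and
   single-precision membrane arithmetic, alongside a double-precision
   reference mode.
2. **A discrete-event virtual prototype** of the cluster: parallel workers
   with a `(NpW + pipeline)/f_clk` compute time, two DRAM channels serving
   padded synaptic-list lookups (`t_mem = t_lat + n_bytes/BW_max`),
   ring-buffer ports with back-pressure, per-axis link latencies, two-stage
   broadcast routing, and neighbor-to-neighbor two-phase synchronization.
   In functional mode the prototype runs the real dynamics and produces spike
   trains bit-identical to the engine for *any* performance parameters.
3. **A static estimator** that prices the broadcast interconnect in
   expectation: per-node bandwidth = neurons/node × firing rate ×
   acceleration × message size × (nodes − 1), with exactly-once delivery in
   at most two hops.

Around these sit a scaled cortical-microcircuit generator (77,169 neurons in
8 populations at full scale, ~0.3 billion synapses, DC-emulated external
drive), the calibration experiments that isolate each hardware bottleneck
(silent nets, autospike nets, memory sweeps) together with their
difference-formula parameter extractions, and the spike-statistics
validation layer (rates, CV of inter-spike intervals, Pearson correlations
of 2-ms-binned trains, corridor comparison, energy per synaptic event
`E = P·Δt/(S·f_o)`, acceleration `a = n·h/τ`).

## Worked example

Generate a 2%-scale microcircuit, simulate 3 s of biological time in
fixed-point mode, compute validation statistics, then emulate the same
network on a 2×2 cluster:

```python
import spikemesh as sm

net = sm.generate_microcircuit(neuron_scale=0.02, synapse_scale=0.02, seed=1)
print(f"neurons: {net.n_neurons}   synapses: {net.connectome.n_synapses}")

raster = sm.run_network(net, n_steps=30_000, mode="fixed")
stats = sm.compute_stats(raster, discard_steps=10_000, pop_of=net.pop_of)
print(f"spikes: {raster.n_spikes}   mean rate: {stats.mean_rate_hz:.2f} Hz")

mapping = sm.map_round_robin(net.n_neurons, 4)
tl, ras = sm.simulate(net, mapping, sm.Topology(2, 2), sm.PerfParams(),
                      n_steps=2_000, mode="functional", seed=1)
print(f"predicted acceleration: {tl.predicted_acceleration:.1f}x   "
      f"late spikes: {tl.total_late_spikes}")
```

Output:

```
neurons: 1544   synapses: 119527
spikes: 44230   mean rate: 9.50 Hz
predicted acceleration: 31.9x   late spikes: 0
```

The 1,544 neurons are the eight cortical populations scaled to 2%, firing
asynchronously at population rates between ~4 Hz (L2/3E, L6E) and ~20 Hz
(inhibitory populations) after the 1 s transient is discarded.  The virtual
prototype predicts that a 2×2 cluster with default hardware parameters
(189.383 MHz workers, 30 pipeline stages, 800 ns memory latency, 794/815 ns
row/column link latency, two syncs per timestep) would run this network
31.9× faster than biological real time, and the synchronization protocol
delivered every spike before its consumption step (`late spikes: 0`).

There is also a CLI mirroring the library:

```bash
spikemesh --seed 1 --config run.yaml generate     # connectome images + config
spikemesh --seed 1 --config run.yaml simulate     # functional engine -> raster
spikemesh --seed 1 --config run.yaml emulate      # virtual prototype -> timeline
spikemesh static-bw --rate-hz 3.2043 --accel 20.36
spikemesh calibrate                               # bottleneck-isolation suite
spikemesh stats raster.tsv
spikemesh compare test.tsv ref1.tsv ref2.tsv ref3.tsv
spikemesh metrics --power-w 928.9 --bio-seconds 900 --accel 20.36 \
    --total-spikes 222545972 --mean-fanout 3880
```

## Layout

| module | contents |
| --- | --- |
| `spikemesh.snn_core` | LIF/CUBA propagators, neuron stepping, ring buffers, fixed-point weights, vectorized network engine |
| `spikemesh.connectome` | microcircuit generator, round-robin mapping, padded synaptic-list images, record codec |
| `spikemesh.interconnect` | grid topology, two-stage broadcast, static bandwidth estimator |
| `spikemesh.virtual_prototype` | discrete-event cluster model (workers, memory, router, links, sync) |
| `spikemesh.calibration` | bottleneck-isolation networks and parameter-extraction formulas |
| `spikemesh.analysis` | spike rasters, rates/CV/correlation statistics, corridor comparison, energy/acceleration metrics |
| `spikemesh.io`, `spikemesh.cli` | YAML run configs, raster/image serialization, command-line entry points |

See `docs/methods.md` for the model descriptions, parameter defaults and
numerical conventions.
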