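"""Spike-train statistics and the validation/efficiency metrics.

Correctness of an accelerated run is judged the way it is done for chaotic
spiking networks, where spike-by-spike comparison across arithmetic variants
is meaningless: distribution-level spike statistics — time-averaged firing
rates, coefficients of variation (CV) of inter-spike intervals, and Pearson
correlations of binned spike trains for a random sample of neurons — are
compared against a corridor spanned by reference simulations with different
seeds.  The first 10,000 timesteps are discarded to exclude transients.

Scalar metrics: total-spike-count deviation between two runs, the
acceleration factor a = n*h/tau, and the energy per synaptic event
E = P*dt / (S * f_o).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeRaster",
    "StatsReport",
    "compute_stats",
    "corridor_compare",
    "spike_count_deviation",
    "energy_per_synaptic_event",
    "acceleration_factor",
    "CORRIDOR_QUANTILES",
]

#: quantiles summarizing a per-neuron statistic distribution for corridor
#: comparison (robust against per-bin histogram noise at finite sample size)
CORRIDOR_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass
class SpikeRaster:
    """Spike events as parallel (neuron, timestep) arrays, canonically sorted."""

    neuron: np.ndarray
    step: np.ndarray
    n_neurons: int
    n_steps: int
    h: float = 0.1  # ms

    def __post_init__(self) -> None:
        self.neuron = np.asarray(self.neuron, dtype=np.int64)
        self.step = np.asarray(self.step, dtype=np.int64)
        if self.neuron.shape != self.step.shape:
            raise ValueError("neuron and step arrays must have equal length")
        if self.step.size:
            if self.step.min() < 0 or self.step.max() >= self.n_steps:
                raise ValueError("timesteps outside [0, n_steps)")
            if self.neuron.min() < 0 or self.neuron.max() >= self.n_neurons:
                raise ValueError("neuron ids outside [0, n_neurons)")
            order = np.lexsort((self.neuron, self.step))
            self.neuron = self.neuron[order]
            self.step = self.step[order]

    @property
    def n_spikes(self) -> int:
        return len(self.step)

    def counts(self) -> np.ndarray:
        return np.bincount(self.neuron, minlength=self.n_neurons)

    def window(self, start_step: int) -> "SpikeRaster":
        keep = self.step >= start_step
        return SpikeRaster(self.neuron[keep], self.step[keep] - start_step,
                           self.n_neurons, self.n_steps - start_step, self.h)


@dataclass
class StatsReport:
    """Per-neuron validation statistics of one run."""

    rates_hz: np.ndarray            # biological spikes/s, per neuron
    cv_isi: np.ndarray              # nan where fewer than 2 spikes
    pearson: np.ndarray             # (sample, sample) correlation matrix
    sampled_neurons: np.ndarray
    discard_steps: int
    bin_ms: float
    pop_of: np.ndarray | None = None

    @property
    def mean_rate_hz(self) -> float:
        return float(self.rates_hz.mean())

    def pearson_offdiag(self) -> np.ndarray:
        m = self.pearson
        iu = np.triu_indices_from(m, k=1)
        vals = m[iu]
        return vals[~np.isnan(vals)]


def compute_stats(raster: SpikeRaster, discard_steps: int = 10_000,
                  sample: int = 200, bin_ms: float = 2.0, seed: int = 0,
                  pop_of: np.ndarray | None = None) -> StatsReport:
    """Rates, CV of inter-spike intervals, and pairwise Pearson coefficients.

    Statistics are computed on the window after ``discard_steps``; the
    ``sample`` neurons entering the correlation matrix are drawn
    seed-deterministically.  CV is reported as nan for neurons with fewer
    than two post-discard spikes.
    """
    if raster.n_steps <= discard_steps:
        raise ValueError("raster shorter than the discard window")
    win = raster.window(discard_steps)
    duration_s = win.n_steps * win.h * 1e-3

    counts = win.counts()
    rates = counts / duration_s

    cv = np.full(win.n_neurons, np.nan)
    order = np.lexsort((win.step, win.neuron))  # group by neuron, time-sorted
    nrn, stp = win.neuron[order], win.step[order]
    starts = np.searchsorted(nrn, np.arange(win.n_neurons))
    ends = np.searchsorted(nrn, np.arange(win.n_neurons) + 1)
    for g in np.flatnonzero(counts >= 2):
        isi = np.diff(stp[starts[g]:ends[g]]).astype(float)
        m = isi.mean()
        cv[g] = isi.std() / m if m > 0 else np.nan

    rng = np.random.default_rng(seed)
    k = min(sample, win.n_neurons)
    sampled = np.sort(rng.choice(win.n_neurons, size=k, replace=False))
    bin_steps = max(int(round(bin_ms / win.h)), 1)
    n_bins = win.n_steps // bin_steps
    binned = np.zeros((k, n_bins))
    sel = np.isin(win.neuron, sampled)
    pos = np.searchsorted(sampled, win.neuron[sel])
    b = win.step[sel] // bin_steps
    ok = b < n_bins
    np.add.at(binned, (pos[ok], b[ok]), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.corrcoef(binned)
    if np.ndim(pearson) == 0:
        pearson = np.array([[1.0]])
    np.fill_diagonal(pearson, 1.0)

    return StatsReport(rates_hz=rates, cv_isi=cv, pearson=pearson,
                       sampled_neurons=sampled, discard_steps=discard_steps,
                       bin_ms=bin_ms, pop_of=pop_of)


def _quantiles(values: np.ndarray) -> np.ndarray:
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        return np.full(len(CORRIDOR_QUANTILES), np.nan)
    return np.quantile(vals, CORRIDOR_QUANTILES)


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 and b.size == 0:
        return 0.0
    if a.size == 0 or b.size == 0:
        return 1.0
    from scipy import stats

    return float(stats.ks_2samp(a, b).statistic)


def corridor_compare(report: StatsReport, reference_reports: list[StatsReport],
                     statistic: str = "rates") -> dict:
    """Distribution-level comparison against a reference corridor.

    For each population (or the whole network when no population labels are
    attached), the per-neuron distribution of the chosen statistic is
    compared to every reference run by the two-sample Kolmogorov–Smirnov
    distance.  The run lies *inside* the corridor when it is at least as
    close to some reference as the references are to each other — i.e. the
    deviation induced by the arithmetic under test does not exceed the
    deviation between reference seeds.  This is the distributional analogue
    of a min–max envelope that remains meaningful at finite sample sizes,
    where strict per-bin histogram containment is noise-dominated.
    Reported quantiles summarize the distributions for inspection.
    """
    if len(reference_reports) < 2:
        raise ValueError("need at least two reference reports for a corridor")

    def values(rep: StatsReport) -> np.ndarray:
        if statistic == "rates":
            return rep.rates_hz
        if statistic == "cv":
            return rep.cv_isi
        raise ValueError(f"unknown statistic {statistic!r}")

    def pops(rep: StatsReport) -> np.ndarray:
        if rep.pop_of is None:
            return np.zeros(len(values(rep)), dtype=np.int64)
        return rep.pop_of

    test_pops = pops(report)
    for ref in reference_reports:
        if set(np.unique(pops(ref)).tolist()) != set(np.unique(test_pops).tolist()):
            raise ValueError("incompatible populations between runs")

    result = {}
    for p in np.unique(test_pops):
        tv = values(report)[test_pops == p]
        rv = [values(r)[pops(r) == p] for r in reference_reports]
        spread = max(_ks_distance(a, b)
                     for i, a in enumerate(rv) for b in rv[i + 1:])
        dist = min(_ks_distance(tv, r) for r in rv)
        result[int(p)] = {
            "inside": bool(dist <= spread),
            "ks_distance": dist,
            "reference_spread": spread,
            "quantiles": _quantiles(tv),
        }
    result["inside"] = all(v["inside"] for k, v in result.items() if k != "inside")
    return result


def spike_count_deviation(s_test: int, s_ref: int) -> float:
    """Relative total-spike-count deviation in percent, two decimals."""
    if s_ref <= 0:
        raise ValueError("reference spike count must be positive")
    return round(100.0 * abs(s_test - s_ref) / s_ref, 2)


def energy_per_synaptic_event(power_w: float, duration_s: float,
                              total_spikes: int, mean_fanout: float) -> float:
    """Energy per synaptic event in nJ: P * dt / (S * f_o)."""
    if min(power_w, duration_s, total_spikes, mean_fanout) <= 0:
        raise ValueError("all inputs must be positive")
    return power_w * duration_s / (total_spikes * mean_fanout) * 1e9


def acceleration_factor(n_steps: int, h_ms: float, tau_s: float) -> float:
    """Acceleration a = n*h/tau: biological over wall-clock time."""
    if tau_s <= 0:
        raise ValueError("wall-clock duration must be positive")
    return n_steps * h_ms * 1e-3 / tau_s
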