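"""Run configuration, raster and connectome-image serialization.

A run is described by a YAML configuration with four sections mirroring the
parameter taxonomy of the simulators: ``biological`` (rates, scales,
connectivity), ``simulation`` (steps, seed, mode), ``interconnect`` (grid,
bandwidths, latencies) and ``hardware`` (workers, pipeline, memory).
Unknown keys are rejected with their full key path; every run artifact can
embed the fully resolved configuration for reproducibility.

Rasters are stored as delimited text (``neuron_id<TAB>timestep``) with a
small header carrying the raster dimensions.  Connectome memory images are
stored as the raw padded-list record stream behind a 16-byte self-describing
header (magic, version, source count, list length).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
import struct

import numpy as np
import yaml

from .connectome import PaddedListImage, RECORD_BYTES
from .analysis import SpikeRaster
from .interconnect import Topology
from .virtual_prototype import PerfParams

__all__ = [
    "BiologicalConfig",
    "SimulationConfig",
    "InterconnectConfig",
    "HardwareConfig",
    "RunConfig",
    "ConfigError",
    "read_config",
    "write_config",
    "read_raster",
    "write_raster",
    "read_connectome_image",
    "write_connectome_image",
]

IMAGE_MAGIC = b"SMCI"
IMAGE_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the key."""


@dataclass
class BiologicalConfig:
    neuron_scale: float = 1.0
    synapse_scale: float = 1.0
    rate_hz: float = 3.2        # mean biological firing rate (statistical mode)
    h_ms: float = 0.1


@dataclass
class SimulationConfig:
    n_steps: int = 1000
    seed: int = 0
    mode: str = "functional"    # functional | statistical
    dyn_mode: str = "fixed"     # fixed | double


@dataclass
class InterconnectConfig:
    grid_width: int = 7
    grid_height: int = 5
    row_bandwidth_gbps: float = 6.25
    col_bandwidth_gbps: float = 6.0
    row_latency_ns: float = 794.0
    col_latency_ns: float = 815.0

    def to_topology(self) -> Topology:
        return Topology(self.grid_width, self.grid_height,
                        self.row_bandwidth_gbps, self.col_bandwidth_gbps,
                        self.row_latency_ns, self.col_latency_ns)


@dataclass
class HardwareConfig:
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
    msg_bits: int = 128
    sync_count: int | None = None

    def to_perf_params(self) -> PerfParams:
        return PerfParams(
            f_clk_mhz=self.f_clk_mhz, pipeline_depth=self.pipeline_depth,
            n_workers=self.n_workers, max_npw=self.max_npw,
            step_overhead_ns=self.step_overhead_ns,
            mem_t_lat_ns=self.mem_t_lat_ns, mem_bw_gbs=self.mem_bw_gbs,
            mem_channels=self.mem_channels,
            ringbuffer_bw_gbs=self.ringbuffer_bw_gbs,
            spike_local_cost_ns=self.spike_local_cost_ns,
            msg_bits=self.msg_bits, sync_count=self.sync_count,
        )


@dataclass
class RunConfig:
    biological: BiologicalConfig = field(default_factory=BiologicalConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    interconnect: InterconnectConfig = field(default_factory=InterconnectConfig)
    hardware: HardwareConfig = field(default_factory=HardwareConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "biological": BiologicalConfig,
    "simulation": SimulationConfig,
    "interconnect": InterconnectConfig,
    "hardware": HardwareConfig,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in data:
        if key not in _SECTIONS:
            raise ConfigError(f"unknown configuration section {key!r}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        known = {f.name for f in fields(cls)}
        for key in section:
            if key not in known:
                raise ConfigError(f"unknown key {name}.{key}")
        kwargs[name] = cls(**section)
    return RunConfig(**kwargs)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# spike rasters: delimited text
# ---------------------------------------------------------------------------

def write_raster(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={raster.n_neurons} n_steps={raster.n_steps} "
                 f"h={raster.h!r}\n")
        fh.write("neuron_id\ttimestep\n")
        for n, s in zip(raster.neuron, raster.step):
            fh.write(f"{n}\t{s}\n")


def read_raster(path) -> SpikeRaster:
    header = None
    neurons, steps = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    try:
                        kv = dict(tok.split("=") for tok in line[1:].split())
                        header = (int(kv["n_neurons"]), int(kv["n_steps"]),
                                  float(kv["h"]))
                    except (ValueError, KeyError) as e:
                        raise ValueError(f"line {lineno}: malformed header") from e
                continue
            if line.startswith("neuron_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two tab-separated fields")
            try:
                neurons.append(int(parts[0]))
                steps.append(int(parts[1]))
            except ValueError as e:
                raise ValueError(f"line {lineno}: non-integer event") from e
    if header is None:
        raise ValueError("raster file lacks its header line")
    n_neurons, n_steps, h = header
    return SpikeRaster(np.array(neurons, dtype=np.int64),
                       np.array(steps, dtype=np.int64),
                       n_neurons=n_neurons, n_steps=n_steps, h=h)


# ---------------------------------------------------------------------------
# connectome memory images: binary records behind a self-describing header
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sHHII")  # magic, version, pad, n_sources, list_len


def write_connectome_image(image: PaddedListImage, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(IMAGE_MAGIC, IMAGE_VERSION, 0,
                              image.n_sources, image.list_len))
        fh.write(image.to_bytes())


def read_connectome_image(path) -> PaddedListImage:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size:
        raise ValueError("truncated connectome image: missing header")
    magic, version, _pad, n_sources, list_len = _HEADER.unpack_from(raw)
    if magic != IMAGE_MAGIC:
        raise ValueError(f"bad magic {magic!r}")
    if version != IMAGE_VERSION:
        raise ValueError(f"unsupported image version {version}")
    body = raw[_HEADER.size:]
    expected = n_sources * list_len * RECORD_BYTES
    if len(body) != expected:
        raise ValueError(f"truncated connectome image: expected {expected} "
                         f"record bytes, found {len(body)}")
    rec = np.frombuffer(
        body, dtype=[("t", "<u2"), ("d", "u1"), ("p", "u1"), ("w", "<i4")]
    ).reshape(n_sources, list_len)
    return PaddedListImage(
        n_sources=n_sources, list_len=list_len,
        target=rec["t"].copy(), delay=rec["d"].copy(), weight=rec["w"].copy(),
    )
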