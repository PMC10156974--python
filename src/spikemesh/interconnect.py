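"""Row/column-connected grid topology, two-stage broadcast, static bandwidth.

Nodes sit on a ``width x height`` grid and every node is directly linked to
all nodes sharing its row (x axis) and all sharing its column (y axis), so a
node has ``(width-1) + (height-1)`` neighbors.  Spikes are broadcast in two
stages: stage 1 delivers to the whole row and column of the source; stage 2
has every stage-1 recipient in the source's *column* forward along its own
row.  Every node is reached exactly once and the worst case is two hops.

The static bandwidth estimator prices this routing in expectation — no
queueing, no sampling: each node emits spikes at (neurons x biological rate x
acceleration) per wall-clock second, every spike reaches every other node
exactly once as one fixed-size message.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Link",
    "SpikeMessage",
    "BandwidthReport",
    "broadcast_route",
    "static_bandwidth",
    "ENCODING_OVERHEAD",
]

#: 64/66b line-code efficiency folded into effective link bandwidth
ENCODING_OVERHEAD = 64.0 / 66.0

ROW_BW_GBPS = 6.25   # SFP+ links along rows
COL_BW_GBPS = 6.0    # SATA links along columns


@dataclass(frozen=True)
class Link:
    node_a: int
    node_b: int
    axis: str            # "row" (same y) or "col" (same x)
    bandwidth_gbps: float
    latency_ns: float


@dataclass(frozen=True)
class SpikeMessage:
    """128-bit network packet; sync and config packets share the same size."""

    kind: str = "spike"            # spike | sync | config
    source_neuron: int = 0
    origin_step: int = 0
    size_bits: int = 128

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "sync", "config"):
            raise ValueError(f"unknown packet kind {self.kind!r}")


@dataclass
class Topology:
    """Grid with row/column cliques. Node id = y * width + x."""

    width: int
    height: int
    row_bandwidth_gbps: float = ROW_BW_GBPS
    col_bandwidth_gbps: float = COL_BW_GBPS
    row_latency_ns: float = 794.0
    col_latency_ns: float = 815.0
    links: list[Link] = field(init=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        links = []
        for y in range(self.height):
            for x1 in range(self.width):
                for x2 in range(x1 + 1, self.width):
                    links.append(Link(self.node_id(x1, y), self.node_id(x2, y),
                                      "row", self.row_bandwidth_gbps,
                                      self.row_latency_ns))
        for x in range(self.width):
            for y1 in range(self.height):
                for y2 in range(y1 + 1, self.height):
                    links.append(Link(self.node_id(x, y1), self.node_id(x, y2),
                                      "col", self.col_bandwidth_gbps,
                                      self.col_latency_ns))
        self.links = links

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    def node_id(self, x: int, y: int) -> int:
        return y * self.width + x

    def coords(self, node: int) -> tuple[int, int]:
        return node % self.width, node // self.width

    def neighbors(self, node: int) -> list[int]:
        x, y = self.coords(node)
        row = [self.node_id(xx, y) for xx in range(self.width) if xx != x]
        col = [self.node_id(x, yy) for yy in range(self.height) if yy != y]
        return row + col

    def axis_of(self, a: int, b: int) -> str:
        xa, ya = self.coords(a)
        xb, yb = self.coords(b)
        if ya == yb and xa != xb:
            return "row"
        if xa == xb and ya != yb:
            return "col"
        raise ValueError(f"nodes {a} and {b} are not linked")


@dataclass
class BandwidthReport:
    per_node_ingress_gbps: np.ndarray
    per_node_egress_gbps: np.ndarray
    per_link_load_gbps: dict
    max_hops: int

    @property
    def max_ingress_gbps(self) -> float:
        return float(self.per_node_ingress_gbps.max()) if len(self.per_node_ingress_gbps) else 0.0


def broadcast_route(src_node: int, topology: Topology) -> dict[int, tuple[int, int]]:
    """Delivery plan of the two-stage broadcast: node -> (hop_count, parent).

    Stage 1 reaches the source's row and column (1 hop, parent = source);
    stage 2 reaches everything else via the stage-1 recipient in the source's
    column that shares the destination's row (2 hops).
    """
    xs, ys = topology.coords(src_node)
    plan: dict[int, tuple[int, int]] = {}
    for x in range(topology.width):
        if x != xs:
            plan[topology.node_id(x, ys)] = (1, src_node)
    for y in range(topology.height):
        if y != ys:
            plan[topology.node_id(xs, y)] = (1, src_node)
    for y in range(topology.height):
        if y == ys:
            continue
        forwarder = topology.node_id(xs, y)
        for x in range(topology.width):
            if x != xs:
                plan[topology.node_id(x, y)] = (2, forwarder)
    return plan


def static_bandwidth(
    topology: Topology,
    neurons_per_node: np.ndarray | int,
    rate_hz: float,
    accel: float,
    msg_bits: int = 128,
) -> BandwidthReport:
    """Expectation-based bandwidth requirement of the broadcast scheme.

    ``rate_hz`` is the mean *biological* firing rate; the wall-clock message
    rate per node is ``neurons x rate x accel``.  Deterministic — no sampling.
    """
    n = topology.n_nodes
    npn = np.broadcast_to(np.asarray(neurons_per_node, dtype=float), (n,))
    if rate_hz < 0 or accel < 0 or msg_bits < 0:
        raise ValueError("rate, acceleration and message size must be >= 0")
    lam = npn * rate_hz * accel  # spike messages per second injected per node

    ingress = np.zeros(n)
    egress = np.zeros(n)
    link_load: dict[tuple[int, int], float] = {}

    def add_link(a: int, b: int, bits_per_s: float) -> None:
        link_load[(a, b)] = link_load.get((a, b), 0.0) + bits_per_s

    max_hops = 0
    for src in range(n):
        plan = broadcast_route(src, topology)
        bits = lam[src] * msg_bits
        for dst, (hops, parent) in plan.items():
            ingress[dst] += bits
            egress[parent] += bits
            add_link(parent, dst, bits)
            max_hops = max(max_hops, hops)

    return BandwidthReport(
        per_node_ingress_gbps=ingress / 1e9,
        per_node_egress_gbps=egress / 1e9,
        per_link_load_gbps={k: v / 1e9 for k, v in link_load.items()},
        max_hops=max_hops,
    )
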