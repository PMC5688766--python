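"""The bridge graph: interval extremities joined by interval, reference and
bridge connections, each connection a pair of antiparallel directed edges.

Interval connections join the tail and head of each interval and carry the
observed CN as weight; reference connections join reference-consecutive
intervals (head_i -- tail_{i+1}) and are unweighted; bridge connections carry
the read support.  Telomeric vertices (outermost extremities of each reference
chromosome) are where valid reconstruction paths may start and end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .segments import (
    Extremity,
    HEAD,
    KaryographError,
    ObservedData,
    ReferenceSegmentation,
    TAIL,
    canonical_pair,
)

INTERVAL = "interval"
REFERENCE = "reference"
BRIDGE = "bridge"


@dataclass(frozen=True)
class Connection:
    """An undirected connection, realized as two antiparallel directed edges
    u->v ("forward") and v->u ("reverse")."""

    kind: str
    u: Extremity
    v: Extremity
    weight: float | None = None

    @property
    def is_self_loop(self) -> bool:
        return self.u == self.v

    def other(self, e: Extremity) -> Extremity:
        return self.v if e == self.u else self.u


@dataclass
class BridgeGraph:
    segmentation: ReferenceSegmentation
    connections: list[Connection] = field(default_factory=list)
    # global normalizers; equal to this graph's own totals unless the graph is
    # a connected component of a larger graph, in which case they are inherited
    total_length: float = 0.0  # L
    total_support: float = 0.0  # mu

    def __post_init__(self) -> None:
        self.telomeres: set[Extremity] = self.segmentation.telomeres()
        self.vertices: list[Extremity] = list(self.segmentation.extremities())
        self._interval_at: dict[Extremity, Connection] = {}
        self._non_interval_at: dict[Extremity, list[Connection]] = {
            v: [] for v in self.vertices
        }
        for c in self.connections:
            if c.kind == INTERVAL:
                for e in (c.u, c.v):
                    if e in self._interval_at:
                        raise KaryographError(f"two interval connections at {e}")
                    self._interval_at[e] = c
            else:
                self._non_interval_at[c.u].append(c)
                if not c.is_self_loop:
                    self._non_interval_at[c.v].append(c)
        if not self.total_length:
            self.total_length = float(self.segmentation.total_length)
        if not self.total_support:
            self.total_support = float(
                sum(c.weight for c in self.bridge_connections())
            )

    # -- typed accessors ---------------------------------------------------
    def interval_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.kind == INTERVAL]

    def reference_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.kind == REFERENCE]

    def bridge_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.kind == BRIDGE]

    def interval_at(self, v: Extremity) -> Connection:
        return self._interval_at[v]

    def non_interval_at(self, v: Extremity) -> list[Connection]:
        return self._non_interval_at[v]

    def interval_length(self, c: Connection) -> int:
        return self.segmentation.length(c.u.chrom, c.u.index)


def build_bridge_graph(
    seg: ReferenceSegmentation, obs: ObservedData
) -> BridgeGraph:
    """Assemble the bridge graph from a segmentation and observed data.

    Interval connections run tail -> head (canonical forward direction =
    traversing the interval in reference orientation); reference connections
    run head_i -> tail_{i+1}.  A bridge equal to a reference adjacency is
    rejected: by definition a bridge is a non-reference adjacency.
    """
    obs.validate_against(seg)
    connections: list[Connection] = []
    for chrom, lengths in seg.chromosomes.items():
        for j in range(1, len(lengths) + 1):
            connections.append(
                Connection(
                    INTERVAL,
                    Extremity(chrom, j, TAIL),
                    Extremity(chrom, j, HEAD),
                    float(obs.cn[(chrom, j)]),
                )
            )
        for j in range(1, len(lengths)):
            connections.append(
                Connection(
                    REFERENCE,
                    Extremity(chrom, j, HEAD),
                    Extremity(chrom, j + 1, TAIL),
                )
            )
    seen: set[tuple[Extremity, Extremity]] = set()
    for b in obs.bridges:
        pair = canonical_pair(*b.pair)
        if pair in seen:
            raise KaryographError(f"duplicate bridge {pair}")
        seen.add(pair)
        connections.append(Connection(BRIDGE, pair[0], pair[1], float(b.support)))
    return BridgeGraph(seg, connections)


def connected_components(g: BridgeGraph) -> list[BridgeGraph]:
    """Split the graph into maximal connected subgraphs over the undirected
    connection structure.  Reference edges chain all intervals of a chromosome,
    so every component contains whole chromosomes; each component inherits the
    global normalizers L and mu so per-component discordance scores add up to
    the full-graph score."""
    ug = nx.Graph()
    ug.add_nodes_from(g.vertices)
    for c in g.connections:
        ug.add_edge(c.u, c.v)
    out: list[BridgeGraph] = []
    comps = sorted(nx.connected_components(ug), key=lambda vs: min(vs))
    for vs in comps:
        chroms = sorted({v.chrom for v in vs})
        sub_seg = ReferenceSegmentation(
            {c: list(g.segmentation.chromosomes[c]) for c in chroms}
        )
        sub_conns = [c for c in g.connections if c.u in vs]
        out.append(
            BridgeGraph(
                sub_seg,
                sub_conns,
                total_length=g.total_length,
                total_support=g.total_support,
            )
        )
    return out
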