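"""The undirected, weighted analysis graph and its SV motif enumeration.

The assembler's GFA stores every adjacency as an oriented link, and each link
has a reverse-complement twin describing the same double-stranded junction
(from ``a,o1`` to ``b,o2`` versus from ``b,not-o2`` to ``a,not-o1``).  The
analysis graph collapses each such twin pair to ONE edge occurrence —
mirroring Bandage's "single" rendering — and counts the remaining genuinely
parallel links as integer edge weights.  Self-loops are kept: they are the
signature of tandem duplications.

Motifs consumed by the caller:

* triangles — three mutually adjacent nodes (an indel bubble with its
  bypass edge);
* squares — simple 4-cycles, reported with their opposite-pair structure
  (the double-bubble left by a deletion plus insertion at one locus);
* self-loops and weight >= 2 parallel edges (tandem duplication loops).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .errors import GraphSVError
from .graphio import AssemblyGraph, LinkRecord, SegmentRecord

_FLIP = {"+": "-", "-": "+"}

#: An undirected edge key: (u, v) with u <= v; u == v for self-loops.
EdgeKey = tuple[str, str]


def edge_key(u: str, v: str) -> EdgeKey:
    return (u, v) if u <= v else (v, u)


def canonical_link(link: LinkRecord) -> tuple[str, str, str, str]:
    """Canonical form of a link under reverse-complement twin equivalence.

    A link and its twin describe the same junction; the canonical key is the
    lexicographically smaller of the two oriented tuples, so twins collide
    and genuinely parallel links stay distinct.
    """
    fwd = (link.from_name, link.from_orient, link.to_name, link.to_orient)
    twin = (link.to_name, _FLIP[link.to_orient], link.from_name, _FLIP[link.from_orient])
    return min(fwd, twin)


@dataclass
class CollapsedGraph:
    """Undirected weighted analysis graph.

    Wraps a :class:`networkx.Graph` (self-loops allowed).  Node attributes:
    ``length`` (bp) and ``members`` (the 1–2 GFA segments the node
    represents).  Edge attribute ``weight`` counts distinct canonical links.
    """

    nx_graph: nx.Graph = field(default_factory=nx.Graph)
    segment_node: dict[str, str] = field(default_factory=dict)

    def nodes(self) -> list[str]:
        return list(self.nx_graph.nodes)

    def node_length(self, node: str) -> int:
        return self.nx_graph.nodes[node]["length"]

    def members(self, node: str) -> tuple[str, ...]:
        return self.nx_graph.nodes[node]["members"]

    def edges(self) -> list[EdgeKey]:
        return [edge_key(u, v) for u, v in self.nx_graph.edges]

    def weight(self, u: str, v: str) -> int:
        return self.nx_graph.edges[u, v]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self.nx_graph.has_edge(u, v)

    def neighbors(self, node: str, include_self: bool = False) -> list[str]:
        return [
            n for n in self.nx_graph.neighbors(node) if include_self or n != node
        ]

    def node_for_segment(self, segment: str) -> str:
        return self.segment_node[segment]


def collapse(
    graph: AssemblyGraph,
    pairing: Mapping[str, str] | None = None,
) -> CollapsedGraph:
    """Build the analysis graph from a parsed GFA.

    ``pairing`` optionally maps segments to their explicit complement
    partners (for assemblers that emit both strands as separate records);
    each complementary pair becomes one node named after the
    lexicographically smaller member.  By default every segment is its own
    node, matching assemblers that store one record per double-stranded
    sequence.  A link and its reverse-complement twin count as one edge
    occurrence; remaining parallel links increment the edge weight.
    """
    pairing = dict(pairing or {})
    # validate: symmetric, no segment with >1 partner
    for seg, partner in list(pairing.items()):
        if pairing.get(partner, seg) != seg:
            raise GraphSVError(
                f"pairing maps {seg!r}->{partner!r} but {partner!r}->{pairing[partner]!r}"
            )
        pairing[partner] = seg

    collapsed = CollapsedGraph()
    g = collapsed.nx_graph
    for name, seg in graph.segments.items():
        partner = pairing.get(name)
        if partner is not None and partner not in graph.segments:
            raise GraphSVError(f"pairing references unknown segment {partner!r}")
        node = name if partner is None else min(name, partner)
        collapsed.segment_node[name] = node
        if node not in g:
            members = (name,) if partner is None else tuple(sorted((name, partner)))
            g.add_node(node, length=seg.length, members=members)

    canonical = {canonical_link(link) for link in graph.links}
    for from_name, _, to_name, _ in sorted(canonical):
        u = collapsed.segment_node[from_name]
        v = collapsed.segment_node[to_name]
        if g.has_edge(u, v):
            g.edges[u, v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return collapsed


def to_assembly_graph(graph: CollapsedGraph) -> AssemblyGraph:
    """Re-express a collapsed graph as a GFA-level assembly graph.

    One segment per node (sequence-free), and ``weight`` parallel links per
    edge realised as distinct non-twin orientation combinations.  Used for
    round-trip/idempotence checks; weights above the number of distinct
    orientation classes (4 between distinct nodes, 3 on a self-loop) cannot
    be re-expressed and raise.
    """
    asm = AssemblyGraph()
    for node in sorted(graph.nodes()):
        asm.segments[node] = SegmentRecord(name=node, length=graph.node_length(node))
    pair_combos = [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")]
    loop_combos = [("+", "+"), ("+", "-"), ("-", "+")]
    for u, v in sorted(graph.edges()):
        w = graph.weight(u, v)
        combos = loop_combos if u == v else pair_combos
        if w > len(combos):
            raise GraphSVError(f"edge ({u},{v}) weight {w} not expressible in GFA")
        for fo, to in combos[:w]:
            asm.links.append(LinkRecord(u, fo, v, to))
    return asm


def enumerate_triangles(graph: CollapsedGraph) -> set[frozenset[str]]:
    """All unordered triples of mutually adjacent nodes (self-loops ignored)."""
    triangles: set[frozenset[str]] = set()
    for u, v in graph.nx_graph.edges:
        if u == v:
            continue
        common = set(graph.neighbors(u)) & set(graph.neighbors(v))
        for w in common:
            triangles.add(frozenset((u, v, w)))
    return triangles


def canonical_cycle(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
    """Canonical form of the 4-cycle a-b-c-d-a: smallest rotation/reflection.

    Opposite pairs {a,c} and {b,d} are preserved: the canonical tuple starts
    at the smallest node, keeps its opposite in position 2, and orders the
    other pair ascending.
    """
    nodes = (a, b, c, d)
    start = min(nodes)
    i = nodes.index(start)
    opp = nodes[(i + 2) % 4]
    other = sorted((nodes[(i + 1) % 4], nodes[(i + 3) % 4]))
    return (start, other[0], opp, other[1])


def enumerate_squares(graph: CollapsedGraph) -> set[tuple[str, str, str, str]]:
    """All simple 4-cycles on distinct nodes, canonicalised.

    Chords are permitted: a 4-cycle inside a denser subgraph still counts.
    For every unordered node pair the cycle is found by taking two distinct
    common neighbours; the pair and the two common neighbours form the two
    opposite pairs of the square.
    """
    squares: set[tuple[str, str, str, str]] = set()
    nodes = sorted(graph.nodes())
    for a, c in combinations(nodes, 2):
        common = sorted(
            set(graph.neighbors(a)) & set(graph.neighbors(c)) - {a, c}
        )
        for b, d in combinations(common, 2):
            squares.add(canonical_cycle(a, b, c, d))
    return squares


def self_loops(graph: CollapsedGraph) -> list[tuple[str, EdgeKey]]:
    """All self-loop edges as (node, edge-key) pairs, sorted by node."""
    return [(u, (u, u)) for u in sorted(graph.nodes()) if graph.has_edge(u, u)]


def multi_edges(graph: CollapsedGraph, min_weight: int = 2) -> list[EdgeKey]:
    """Non-loop edges with weight >= ``min_weight`` (duplication candidates)."""
    return sorted(
        edge_key(u, v)
        for u, v in graph.nx_graph.edges
        if u != v and graph.nx_graph.edges[u, v]["weight"] >= min_weight
    )
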