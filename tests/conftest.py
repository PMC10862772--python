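"""Shared fixtures: tiny handwritten graphs and alignment files."""

from __future__ import annotations

import pytest

from graphsv import collapse, parse_gfa


def write_text(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return path


def gaf_line(read_id, path_str, plen, pstart, pend, read_len=None, mapq=60):
    read_len = read_len if read_len is not None else pend - pstart
    return (
        f"{read_id}\t{read_len}\t0\t{read_len}\t+\t{path_str}"
        f"\t{plen}\t{pstart}\t{pend}\t{read_len}\t{read_len}\t{mapq}"
    )


@pytest.fixture
def two_segment_graph(tmp_path):
    """s1 (4 bp) -- s2 (6 bp), one link, plus a self-loop on s1."""
    gfa = write_text(
        tmp_path / "two.gfa",
        [
            "H\tVN:Z:1.0",
            "S\ts1\t*\tLN:i:4",
            "S\ts2\t*\tLN:i:6",
            "L\ts1\t+\ts2\t+\t0M",
            "L\ts1\t+\ts1\t+\t0M",
        ],
    )
    return collapse(parse_gfa(gfa))


def collapsed_from_edges(edges, lengths=None):
    """Build a CollapsedGraph directly from (u, v[, weight]) tuples."""
    import networkx as nx

    from graphsv.graph import CollapsedGraph

    g = CollapsedGraph()
    nodes = sorted({n for e in edges for n in e[:2]})
    for n in nodes:
        length = (lengths or {}).get(n, 100)
        g.nx_graph.add_node(n, length=length, members=(n,))
        g.segment_node[n] = n
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else 1
        g.nx_graph.add_edge(u, v, weight=w)
    return g
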