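"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the rule definitions using the standard
library only (itertools/statistics/math), deliberately avoiding the code
paths — and the numpy routines — used by the package itself.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations, permutations

ABS_TOL = 1e-9  # same machine-noise guard as the caller


def brute_median(values):
    return statistics.median(values)


def brute_pop_sd(values, ddof: int = 0):
    mean = sum(values) / len(values)
    denom = len(values) - ddof
    return math.sqrt(sum((v - mean) ** 2 for v in values) / denom)


def brute_outliers(values, ddof: int = 0):
    med = brute_median(values)
    sd = brute_pop_sd(values, ddof)
    idx = tuple(
        i for i, v in enumerate(values) if abs(v - med) > sd and abs(v - med) > ABS_TOL
    )
    return idx, med, sd


def brute_canonical_links(links):
    """Distinct links under reverse-complement twin equivalence.

    ``links`` are (from, from_orient, to, to_orient) tuples; the oracle
    generates both forms of each link explicitly and dedupes via frozensets
    of the two forms.
    """
    flip = {"+": "-", "-": "+"}
    classes = set()
    for a, oa, b, ob in links:
        twin = (b, flip[ob], a, flip[oa])
        classes.add(frozenset(((a, oa, b, ob), twin)))
    return classes


def brute_triangles(nodes, has_edge):
    """All mutually adjacent triples by scanning every 3-subset."""
    return {
        frozenset(t)
        for t in combinations(sorted(nodes), 3)
        if has_edge(t[0], t[1]) and has_edge(t[1], t[2]) and has_edge(t[0], t[2])
    }


def brute_squares(nodes, has_edge):
    """All simple 4-cycles by scanning every ordering of every 4-subset.

    Each found cycle is recorded as its unordered pair of opposite pairs,
    which identifies the cycle up to rotation/reflection.
    """
    squares = set()
    for quad in combinations(sorted(nodes), 4):
        for perm in permutations(quad):
            a, b, c, d = perm
            if has_edge(a, b) and has_edge(b, c) and has_edge(c, d) and has_edge(d, a):
                squares.add(frozenset((frozenset((a, c)), frozenset((b, d)))))
    return squares


def square_key(cycle):
    """Opposite-pair key of a cycle given in cycle order (for comparison)."""
    a, b, c, d = cycle
    return frozenset((frozenset((a, c)), frozenset((b, d))))


def brute_calls(nodes, edges, node_lfc, edge_lfc, steps, ddof: int = 0):
    """Full reimplementation of the per-step calling rules.

    ``edges`` maps unordered (u, v) keys (u <= v) to weights.  Returns the
    deduplicated set of (sv_type, step, frozenset(called_nodes)).
    """

    def has_edge(u, v):
        return u != v and (min(u, v), max(u, v)) in edges

    triangles = brute_triangles(nodes, has_edge)
    square_pairs = brute_squares(nodes, has_edge)
    calls = set()
    for step in steps:
        nl = node_lfc[step]
        el = edge_lfc[step]
        claimed = set()
        for tri in triangles:
            tri = sorted(tri)
            values = [nl[n] for n in tri]
            idx, med, _ = brute_outliers(values, ddof)
            if len(idx) == 1:
                sv = "insertion" if values[idx[0]] > med else "deletion"
                calls.add((sv, step, frozenset((tri[idx[0]],))))
                claimed.add(tri[idx[0]])
        for pairing in square_pairs:
            (a, c), (b, d) = [sorted(p) for p in sorted(pairing, key=sorted)]
            cycle = (a, b, c, d)
            values = [nl[n] for n in cycle]
            idx, med, _ = brute_outliers(values, ddof)
            hit = None
            if len(idx) == 1:
                hit = idx
            elif len(idx) == 2 and (idx[1] - idx[0]) == 2:
                lo, hi = values[idx[0]], values[idx[1]]
                if (lo - med) * (hi - med) < 0:
                    hit = idx
            if hit is not None:
                called = frozenset(cycle[i] for i in hit)
                calls.add(("complex_indel", step, called))
                claimed.update(called)
        dup_claimed = set(claimed)
        for (u, v), weight in sorted(edges.items()):
            if u == v and el[(u, v)] > 1.0:
                calls.add(("tandem_duplication", step, frozenset((u,))))
                dup_claimed.add(u)
        for (u, v), weight in sorted(edges.items()):
            if u == v or weight < 2 or el[(u, v)] <= 1.0:
                continue
            if nl[u] == nl[v]:
                target = min(u, v)
            else:
                target = u if nl[u] > nl[v] else v
            if target in dup_claimed:
                continue
            calls.add(("tandem_duplication", step, frozenset((target,))))
            dup_claimed.add(target)
    return calls


def per_base_depth(node_lengths, records):
    """Per-base depth arrays from alignment records (the coverage oracle).

    ``records`` carry .path (segment, orient) pairs and bp offsets
    .path_start/.path_end on the concatenated path.
    """
    arrays = {n: [0] * length for n, length in node_lengths.items()}
    for rec in records:
        offset = 0
        for seg, _ in rec.path:
            length = node_lengths[seg]
            lo = max(rec.path_start - offset, 0)
            hi = min(rec.path_end - offset, length)
            for i in range(lo, hi):
                arrays[seg][i] += 1
            offset += length
    return arrays
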