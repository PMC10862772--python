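"""Motif-based structural variant calling on log-fold-change vectors.

For each consecutive step pair the caller scans the analysis graph:

* every triangle is tested for a single log-fold-change outlier — an
  outlier above the triangle's median calls an insertion, below calls a
  deletion (the bubble's variant node thrives or declines while its two
  flanks move together);
* every square (simple 4-cycle) calls a complex indel when it holds exactly
  one outlier, or exactly two outliers sitting at opposite cycle positions
  with one above and one below the median (the old allele declining while
  the new one rises at the same locus);
* tandem duplications come from edges: any self-loop whose edge log fold
  change exceeds 1, or any weight >= 2 parallel edge whose edge log fold
  change exceeds 1 — in the latter case the endpoint with the greater node
  log fold change is called, unless it already carries a call at that step.

An outlier is a value more than one standard deviation from the motif's
median (strict inequality).  The median — not the mean — anchors the test so
a single extreme value cannot drag the centre and flag all three nodes.  The
standard deviation is the population form (divide by n) by default: with
three values the sample form can never place two values beyond one sd, which
would make the square rule's two-outlier branch unreachable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .foldchange import LFCTable
from .graph import CollapsedGraph, edge_key, enumerate_squares, enumerate_triangles, multi_edges, self_loops

SV_TYPES = ("insertion", "deletion", "complex_indel", "tandem_duplication")

#: Edge log-fold-change threshold for tandem duplication (strict >).
DUPLICATION_LFC_THRESHOLD = 1.0

#: Machine-noise guard: deviations from the median at or below this are never
#: outliers.  Mathematically equal lfc values can differ by ~1e-16 after
#: floating-point normalization, making the motif sd ~1e-16 and flagging pure
#: round-off as a variant; 1e-9 is far below any real coverage signal.
OUTLIER_ABS_TOL = 1e-9


@dataclass(frozen=True)
class SVCall:
    """One called structural variant.

    ``step_pair`` is the series index n of the change from sample n-1 to
    sample n.  ``called_nodes`` are the implicated node(s) — one node except
    for two-outlier complex indels.  ``motif_nodes`` spell out the full
    supporting motif.  ``score`` is |outlier - median| for median/sd motifs
    and the edge log fold change for duplications; ``support`` counts the
    motif instances that agreed on this call before deduplication.
    """

    sv_type: str
    step_pair: int
    called_nodes: tuple[str, ...]
    motif: str
    motif_nodes: tuple[str, ...]
    median: float
    sd: float
    outlier_lfc: tuple[float, ...]
    score: float
    support: int = 1


@dataclass(frozen=True)
class OutlierResult:
    median: float
    sd: float
    outliers: tuple[int, ...]


def outliers_of(values: Sequence[float], ddof: int = 0) -> OutlierResult:
    """Median/sd outlier test on a motif's 3 or 4 log-fold-change values.

    The median of four values is the mean of the middle two.  ``ddof=0``
    (population sd) is the default; an index is an outlier iff
    |value - median| > sd, strictly, so a constant vector has none.  The
    deviation must additionally exceed :data:`OUTLIER_ABS_TOL` so that
    floating-point round-off on identical values never flags an outlier.
    """
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    sd = float(np.std(arr, ddof=ddof))
    outliers = tuple(
        i
        for i, v in enumerate(arr)
        if abs(v - med) > sd and abs(v - med) > OUTLIER_ABS_TOL
    )
    return OutlierResult(median=med, sd=sd, outliers=outliers)


def call_triangle(
    triple: Iterable[str],
    lfc: Mapping[str, float],
    step_pair: int,
    ddof: int = 0,
) -> SVCall | None:
    """Insertion/deletion test on one triangle; None unless exactly one outlier."""
    nodes = sorted(triple)
    values = [float(lfc[n]) for n in nodes]
    res = outliers_of(values, ddof=ddof)
    if len(res.outliers) != 1:
        return None
    idx = res.outliers[0]
    value = values[idx]
    sv_type = "insertion" if value > res.median else "deletion"
    return SVCall(
        sv_type=sv_type,
        step_pair=step_pair,
        called_nodes=(nodes[idx],),
        motif="triangle",
        motif_nodes=tuple(nodes),
        median=res.median,
        sd=res.sd,
        outlier_lfc=(value,),
        score=abs(value - res.median),
    )


def call_square(
    cycle: Sequence[str],
    lfc: Mapping[str, float],
    step_pair: int,
    ddof: int = 0,
) -> SVCall | None:
    """Complex-indel test on one 4-cycle given in cycle order.

    Calls on exactly one outlier, or on exactly two outliers at opposite
    cycle positions (no cycle edge between them) straddling the median.
    """
    values = [float(lfc[n]) for n in cycle]
    res = outliers_of(values, ddof=ddof)
    called: tuple[int, ...] | None = None
    if len(res.outliers) == 1:
        called = res.outliers
    elif len(res.outliers) == 2:
        i, j = res.outliers
        opposite = (j - i) % 4 == 2
        straddle = (values[i] - res.median) * (values[j] - res.median) < 0
        if opposite and straddle:
            called = res.outliers
    if called is None:
        return None
    score = max(abs(values[i] - res.median) for i in called)
    return SVCall(
        sv_type="complex_indel",
        step_pair=step_pair,
        called_nodes=tuple(sorted(cycle[i] for i in called)),
        motif="square",
        motif_nodes=tuple(cycle),
        median=res.median,
        sd=res.sd,
        outlier_lfc=tuple(values[i] for i in called),
        score=score,
    )


def call_tandem_duplications(
    graph: CollapsedGraph,
    node_lfc_row: Mapping[str, float],
    edge_lfc_row: Mapping[str, float],
    existing_calls: Sequence[SVCall],
    step_pair: int,
) -> list[SVCall]:
    """Tandem duplication calls for one step pair.

    Scenario 1: self-loop edges with edge log fold change > 1.  Scenario 2:
    weight >= 2 non-loop edges with edge log fold change > 1 — the endpoint
    with the greater node log fold change is called unless it already has a
    call at this step (indels and complex indels take precedence; ties on
    node lfc resolve to the lexicographically smaller node).
    """
    claimed: set[str] = set()
    for call in existing_calls:
        if call.step_pair == step_pair:
            claimed.update(call.called_nodes)
    calls: list[SVCall] = []

    def _edge_id(u: str, v: str) -> str:
        a, b = edge_key(u, v)
        return f"{a}--{b}"

    for node, _ in self_loops(graph):
        value = float(edge_lfc_row[_edge_id(node, node)])
        if value > DUPLICATION_LFC_THRESHOLD:
            calls.append(
                SVCall(
                    sv_type="tandem_duplication",
                    step_pair=step_pair,
                    called_nodes=(node,),
                    motif="self_loop",
                    motif_nodes=(node,),
                    median=math.nan,
                    sd=math.nan,
                    outlier_lfc=(value,),
                    score=value,
                )
            )
            claimed.add(node)
    for u, v in multi_edges(graph):
        value = float(edge_lfc_row[_edge_id(u, v)])
        if value <= DUPLICATION_LFC_THRESHOLD:
            continue
        lfc_u, lfc_v = float(node_lfc_row[u]), float(node_lfc_row[v])
        if lfc_u == lfc_v:
            target = min(u, v)
        else:
            target = u if lfc_u > lfc_v else v
        if target in claimed:
            continue
        calls.append(
            SVCall(
                sv_type="tandem_duplication",
                step_pair=step_pair,
                called_nodes=(target,),
                motif="parallel_edge",
                motif_nodes=(u, v),
                median=math.nan,
                sd=math.nan,
                outlier_lfc=(value,),
                score=value,
            )
        )
        claimed.add(target)
    return calls


def _deduplicate(calls: list[SVCall]) -> list[SVCall]:
    """One call per (called nodes, type, step); keep the best-supported motif.

    The retained motif is the one with the largest |outlier - median| score
    (ties: lexicographically smallest motif node tuple); ``support`` records
    how many motif instances agreed.
    """
    groups: dict[tuple, list[SVCall]] = {}
    order: list[tuple] = []
    for call in calls:
        key = (frozenset(call.called_nodes), call.sv_type, call.step_pair)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(call)
    out = []
    for key in order:
        group = sorted(groups[key], key=lambda c: (-c.score, c.motif_nodes))
        best = group[0]
        out.append(
            SVCall(
                sv_type=best.sv_type,
                step_pair=best.step_pair,
                called_nodes=best.called_nodes,
                motif=best.motif,
                motif_nodes=best.motif_nodes,
                median=best.median,
                sd=best.sd,
                outlier_lfc=best.outlier_lfc,
                score=best.score,
                support=len(group),
            )
        )
    return out


@dataclass
class CallResult:
    """Deduplicated calls plus raw per-motif instance counts per step."""

    calls: list[SVCall]
    motif_counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def summary(self) -> dict[int, dict[str, int]]:
        per_step: dict[int, dict[str, int]] = {}
        for call in self.calls:
            step = per_step.setdefault(call.step_pair, {t: 0 for t in SV_TYPES})
            step[call.sv_type] += 1
        return per_step


def call_all(
    graph: CollapsedGraph,
    lfc: LFCTable,
    ddof: int = 0,
) -> CallResult:
    """Run every motif rule over every step pair.

    Triangles and squares are tested first, then tandem duplications (which
    defer to nodes already called at the step).  Calls agreeing on (nodes,
    type, step) across motifs are merged, keeping the strongest motif and
    recording the pre-merge instance count both on the call (``support``)
    and in ``motif_counts``.
    """
    triangles = sorted(tuple(sorted(t)) for t in enumerate_triangles(graph))
    squares = sorted(enumerate_squares(graph))
    result = CallResult(calls=[])
    for step in lfc.node_lfc.index:
        node_row = lfc.node_lfc.loc[step]
        edge_row = lfc.edge_lfc.loc[step]
        raw: list[SVCall] = []
        for tri in triangles:
            call = call_triangle(tri, node_row, int(step), ddof=ddof)
            if call is not None:
                raw.append(call)
        for sq in squares:
            call = call_square(sq, node_row, int(step), ddof=ddof)
            if call is not None:
                raw.append(call)
        step_calls = _deduplicate(raw)
        step_calls.extend(
            call_tandem_duplications(graph, node_row, edge_row, step_calls, int(step))
        )
        counts: dict[str, int] = {}
        for call in raw + [c for c in step_calls if c.sv_type == "tandem_duplication"]:
            counts[call.motif] = counts.get(call.motif, 0) + 1
        result.motif_counts[int(step)] = counts
        result.calls.extend(step_calls)
    return result
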