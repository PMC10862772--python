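"""Per-sample node coverage and edge traversal counts from GAF alignments.

Node coverage is mean depth per base pair: each alignment deposits depth 1
over the bases of every path segment it covers (interior segments fully,
terminal segments clipped by the alignment's path offsets), and the base
total is divided by node length.  Coverage below the floor (default 1) is
raised to the floor so downstream log ratios stay finite, then rescaled
across the series so that sequencing-depth differences between samples do
not masquerade as abundance shifts.

Edge coverage is a plain traversal count: every consecutive pair of path
segments in a read increments its undirected edge, pooling both directions;
a path step from a segment to itself increments the self-loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import GraphSVError
from .graph import CollapsedGraph, EdgeKey, edge_key
from .graphio import AlignmentRecord

logger = logging.getLogger(__name__)

NormalizationMode = Literal["median_ratio", "reciprocal", "none"]


@dataclass
class SeriesConfig:
    """Sample series layout and coverage/fold-change options.

    ``sample_ids`` fixes the series order: N+1 samples give N step pairs.
    ``bp_totals`` holds total aligned-read base pairs per sample (summed
    read lengths of mapped GAF records), used to derive per-sample
    normalization multipliers.  ``median_ratio`` (default) multiplies each
    sample by m / bp_n where m is the median total, equalising depth across
    the series; ``reciprocal`` applies the inverse bp_n / m;
    ``none`` leaves coverage unscaled.
    """

    sample_ids: tuple[str, ...]
    bp_totals: tuple[float, ...] | None = None
    log_base: float = 2.0
    floor_value: float = 1.0
    normalization_mode: NormalizationMode = "median_ratio"

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        if len(self.sample_ids) < 2:
            raise GraphSVError("a series needs at least 2 samples")
        if self.log_base <= 1:
            raise GraphSVError("log_base must be > 1")
        if self.bp_totals is not None:
            self.bp_totals = tuple(float(b) for b in self.bp_totals)
            if len(self.bp_totals) != len(self.sample_ids):
                raise GraphSVError("bp_totals length must match sample_ids")
            if any(b <= 0 for b in self.bp_totals):
                raise GraphSVError("bp_totals must all be > 0")

    @property
    def n_steps(self) -> int:
        return len(self.sample_ids) - 1


@dataclass
class CoverageTable:
    """Floored, normalized node coverage and raw edge traversal counts.

    ``node_cov``: DataFrame [sample x node] of mean depth per bp.
    ``edge_cov``: DataFrame [sample x edge-id] of integer traversal counts,
    edge ids formatted ``u--v`` with u <= v (``u--u`` for self-loops).
    """

    node_cov: pd.DataFrame
    edge_cov: pd.DataFrame
    off_graph: dict[str, int] = field(default_factory=dict)


def edge_id(key: EdgeKey) -> str:
    return f"{key[0]}--{key[1]}"


def node_coverage(
    alignments: Iterable[AlignmentRecord], graph: CollapsedGraph
) -> pd.Series:
    """Raw mean depth per node from one sample's alignments.

    Terminal path segments are clipped by ``path_start``/``path_end``;
    interior segments contribute their full length.  A path segment absent
    from the graph raises, naming the read and segment.
    """
    base_total = {node: 0.0 for node in graph.nodes()}
    for rec in alignments:
        offset = 0
        for seg_name, _orient in rec.path:
            try:
                node = graph.node_for_segment(seg_name)
            except KeyError:
                raise GraphSVError(
                    f"read {rec.read_id!r}: path segment {seg_name!r} not in graph"
                ) from None
            seg_len = graph.node_length(node)
            lo = max(rec.path_start, offset)
            hi = min(rec.path_end, offset + seg_len)
            if hi > lo:
                base_total[node] += hi - lo
            offset += seg_len
    nodes = sorted(base_total)
    return pd.Series(
        [base_total[n] / graph.node_length(n) for n in nodes],
        index=nodes,
        dtype=float,
    )


def floor_coverage(raw: pd.Series | np.ndarray, floor_value: float = 1.0):
    """Elementwise max(raw, floor) — absent or low-depth nodes read as floor."""
    if isinstance(raw, pd.Series):
        return raw.clip(lower=floor_value)
    return np.maximum(np.asarray(raw, dtype=float), floor_value)


def normalization_multipliers(config: SeriesConfig) -> np.ndarray:
    """Per-sample multipliers from total base pairs.

    ``median_ratio``: m / bp_n (m = median of bp_totals) — equalises depth.
    ``reciprocal``: bp_n / m.  ``none``: all ones.
    """
    if config.normalization_mode == "none" or config.bp_totals is None:
        return np.ones(len(config.sample_ids))
    bp = np.asarray(config.bp_totals, dtype=float)
    if np.any(bp <= 0):
        raise GraphSVError("zero bp total in series")
    m = float(np.median(bp))
    if config.normalization_mode == "median_ratio":
        return m / bp
    if config.normalization_mode == "reciprocal":
        return bp / m
    raise GraphSVError(f"unknown normalization mode {config.normalization_mode!r}")


def normalize_series(cov: pd.DataFrame, config: SeriesConfig) -> pd.DataFrame:
    """Scale each sample's node coverage by its multiplier; re-floor after."""
    mult = normalization_multipliers(config)
    out = cov.mul(pd.Series(mult, index=cov.index), axis=0)
    return out.clip(lower=config.floor_value)


def edge_traversals(
    alignments: Iterable[AlignmentRecord],
    graph: CollapsedGraph,
) -> tuple[pd.Series, int]:
    """Per-edge traversal counts for one sample.

    Returns (counts indexed by edge id, off-graph adjacency count).
    Consecutive path pairs with no corresponding edge are counted and
    logged, not raised: minigraph may route a read across a junction the
    assembler did not keep.
    """
    counts = {edge_id(e): 0 for e in graph.edges()}
    off_graph = 0
    for rec in alignments:
        for (seg_a, _), (seg_b, _) in zip(rec.path, rec.path[1:]):
            u = graph.node_for_segment(seg_a)
            v = graph.node_for_segment(seg_b)
            key = edge_id(edge_key(u, v))
            if key in counts:
                counts[key] += 1
            else:
                off_graph += 1
    if off_graph:
        logger.warning("%d off-graph adjacencies in alignments", off_graph)
    ids = sorted(counts)
    return pd.Series([counts[i] for i in ids], index=ids, dtype=int), off_graph


def compute_coverage(
    graph: CollapsedGraph,
    per_sample_alignments: Sequence[Iterable[AlignmentRecord]],
    config: SeriesConfig,
) -> tuple[CoverageTable, SeriesConfig]:
    """Full coverage pass over the series.

    Each sample's alignment stream is consumed once for node depth, edge
    traversals and the sample's total aligned bases.  If the config carries
    no ``bp_totals`` they are measured here (summed read lengths of mapped
    records) before normalization.  Returns the coverage table and the
    (possibly updated) config.
    """
    if len(per_sample_alignments) != len(config.sample_ids):
        raise GraphSVError("one alignment stream per sample required")
    node_rows, edge_rows, bp_totals, off_counts = [], [], [], {}
    for sample, stream in zip(config.sample_ids, per_sample_alignments):
        records = list(stream)
        bp_totals.append(float(sum(r.read_length for r in records)))
        node_rows.append(node_coverage(records, graph))
        counts, off = edge_traversals(records, graph)
        edge_rows.append(counts)
        off_counts[sample] = off
    if config.bp_totals is None:
        config = SeriesConfig(
            sample_ids=config.sample_ids,
            bp_totals=tuple(bp_totals),
            log_base=config.log_base,
            floor_value=config.floor_value,
            normalization_mode=config.normalization_mode,
        )
    node_cov = pd.DataFrame(node_rows, index=list(config.sample_ids))
    node_cov = node_cov.clip(lower=config.floor_value)
    node_cov = normalize_series(node_cov, config)
    edge_cov = pd.DataFrame(edge_rows, index=list(config.sample_ids))
    return CoverageTable(node_cov=node_cov, edge_cov=edge_cov, off_graph=off_counts), config
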