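"""Readers and writers for the formats the tool touches.

Assembly graphs arrive as GFA 1.0 (``S``/``L`` records; ``H`` ignored, other
record types skipped with a logged warning).  Read-to-graph alignments arrive
as GAF, the tab-separated format emitted by graph aligners such as minigraph,
whose column 6 encodes an oriented path with ``>``/``<`` prefixes.  Outputs
are a deterministic TSV table of structural-variant calls and per-step-pair
CSV colour overlays in the dialect the Bandage graph viewer expects
(``Name,Colour`` header).

All coordinates are 0-based, half-open (the GAF convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, TextIO

from .errors import GafParseError, GfaParseError

logger = logging.getLogger(__name__)

# Orientation symbols: GFA uses +/-, GAF paths use >/<.
_GAF_STEP_RE = re.compile(r"([><])([^><]+)")
_ORIENTS = {"+", "-"}

#: Diverging colour ramp for Bandage overlays: coverage loss (negative log
#: fold change) in blue, gain in red, zero at the neutral midpoint.
BANDAGE_LOW = "#2166AC"
BANDAGE_MID = "#F7F7F7"
BANDAGE_HIGH = "#B2182B"


@dataclass(frozen=True)
class SegmentRecord:
    """One GFA ``S`` record: a graph node carrying (or declaring) a sequence.

    ``sequence`` is ``None`` when the GFA stores ``*`` and declares the
    length through an ``LN:i:`` tag, which keeps sequence-free graphs small.
    """

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"segment {self.name!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"segment {self.name!r}: sequence length {len(self.sequence)}"
                f" != declared length {self.length}"
            )


@dataclass(frozen=True)
class LinkRecord:
    """One GFA ``L`` record: an oriented adjacency between two segments."""

    from_name: str
    from_orient: str
    to_name: str
    to_orient: str

    def __post_init__(self) -> None:
        if self.from_orient not in _ORIENTS or self.to_orient not in _ORIENTS:
            raise ValueError("link orientations must be '+' or '-'")


@dataclass
class AssemblyGraph:
    """Raw parsed GFA: segments by name plus the link list, order preserved."""

    segments: dict[str, SegmentRecord] = field(default_factory=dict)
    links: list[LinkRecord] = field(default_factory=list)


@dataclass(frozen=True)
class AlignmentRecord:
    """One GAF line: a read mapped onto an oriented path of segments.

    ``path_start``/``path_end`` are base-pair offsets on the concatenated
    path sequence (0-based, half-open).
    """

    read_id: str
    read_length: int
    path: tuple[tuple[str, str], ...]
    path_start: int
    path_end: int
    residue_matches: int = 0
    mapq: int = 0

    def __post_init__(self) -> None:
        if not self.path:
            raise ValueError(f"read {self.read_id!r}: empty path")
        if not (0 <= self.path_start < self.path_end):
            raise ValueError(
                f"read {self.read_id!r}: invalid path interval "
                f"[{self.path_start}, {self.path_end})"
            )


def _parse_tags(fields: Sequence[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def parse_gfa(path: str | Path) -> AssemblyGraph:
    """Parse a GFA 1.0 file into an :class:`AssemblyGraph`.

    Only ``H``/``S``/``L`` records are honoured; other record types are
    skipped with a logged warning.  Segments with a ``*`` sequence must carry
    an ``LN:i:`` length tag.  Links referencing unknown segments raise.
    """
    graph = AssemblyGraph()
    skipped: dict[str, int] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            if kind == "S":
                graph_segment = _parse_segment(fields, lineno)
                if graph_segment.name in graph.segments:
                    raise GfaParseError(
                        f"line {lineno}: duplicate segment {graph_segment.name!r}"
                    )
                graph.segments[graph_segment.name] = graph_segment
            elif kind == "L":
                graph.links.append(_parse_link(fields, lineno))
            else:
                skipped[kind] = skipped.get(kind, 0) + 1
    for kind, count in sorted(skipped.items()):
        logger.warning("ignored %d GFA record(s) of type %r", count, kind)
    for link in graph.links:
        for name in (link.from_name, link.to_name):
            if name not in graph.segments:
                raise GfaParseError(
                    f"link references unknown segment {name!r}"
                )
    return graph


def _parse_segment(fields: Sequence[str], lineno: int) -> SegmentRecord:
    if len(fields) < 3:
        raise GfaParseError(f"line {lineno}: S record needs >= 3 fields")
    name, seq = fields[1], fields[2]
    tags = _parse_tags(fields[3:])
    try:
        if seq == "*":
            if "LN" not in tags:
                raise GfaParseError(
                    f"line {lineno}: segment {name!r} has no sequence and no LN tag"
                )
            return SegmentRecord(name=name, length=int(tags["LN"]), sequence=None)
        length = int(tags["LN"]) if "LN" in tags else len(seq)
        return SegmentRecord(name=name, length=length, sequence=seq)
    except (ValueError, TypeError) as exc:
        raise GfaParseError(f"line {lineno}: malformed S record: {exc}") from exc


def _parse_link(fields: Sequence[str], lineno: int) -> LinkRecord:
    if len(fields) < 5:
        raise GfaParseError(f"line {lineno}: L record needs >= 5 fields")
    try:
        return LinkRecord(
            from_name=fields[1],
            from_orient=fields[2],
            to_name=fields[3],
            to_orient=fields[4],
        )
    except ValueError as exc:
        raise GfaParseError(f"line {lineno}: malformed L record: {exc}") from exc


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    """Write an :class:`AssemblyGraph` back to GFA 1.0.

    Sequence-free segments are emitted as ``*`` with an ``LN:i:`` tag; links
    get a ``0M`` overlap.  Output order is deterministic (segments by name,
    links in stored order).
    """
    with open(path, "w") as out:
        out.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.segments):
            seg = graph.segments[name]
            seq = seg.sequence if seg.sequence is not None else "*"
            out.write(f"S\t{seg.name}\t{seq}\tLN:i:{seg.length}\n")
        for link in graph.links:
            out.write(
                f"L\t{link.from_name}\t{link.from_orient}"
                f"\t{link.to_name}\t{link.to_orient}\t0M\n"
            )


def parse_path(path_str: str) -> tuple[tuple[str, str], ...]:
    """Turn a GAF path string like ``>s1<s2`` into ((s1, '+'), (s2, '-'))."""
    if not path_str or path_str[0] not in "><":
        raise GafParseError(f"path {path_str!r} lacks >/< orientation prefix")
    steps = _GAF_STEP_RE.findall(path_str)
    consumed = sum(1 + len(s) for _, s in steps)
    if consumed != len(path_str):
        raise GafParseError(f"unparseable GAF path {path_str!r}")
    return tuple((seg, "+" if sym == ">" else "-") for sym, seg in steps)


class GafReader:
    """Streaming GAF parser.

    Iterating yields :class:`AlignmentRecord` in file order.  Unmapped lines
    (``*`` path) and records failing the optional ``min_mapq`` /
    ``min_read_length`` thresholds are skipped; counts are kept on
    ``.skipped_unmapped`` and ``.skipped_filtered`` as the stream is consumed.
    """

    def __init__(
        self,
        path: str | Path,
        min_mapq: int = 0,
        min_read_length: int = 0,
    ) -> None:
        self.path = Path(path)
        self.min_mapq = min_mapq
        self.min_read_length = min_read_length
        self.skipped_unmapped = 0
        self.skipped_filtered = 0

    def __iter__(self) -> Iterator[AlignmentRecord]:
        with open(self.path) as handle:
            yield from self._records(handle)

    def _records(self, handle: TextIO) -> Iterator[AlignmentRecord]:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GafParseError(
                    f"{self.path.name} line {lineno}: GAF needs >= 12 columns"
                )
            if fields[5] == "*":
                self.skipped_unmapped += 1
                continue
            try:
                record = AlignmentRecord(
                    read_id=fields[0],
                    read_length=int(fields[1]),
                    path=parse_path(fields[5]),
                    path_start=int(fields[7]),
                    path_end=int(fields[8]),
                    residue_matches=int(fields[9]),
                    mapq=int(fields[11]),
                )
            except (ValueError, GafParseError) as exc:
                raise GafParseError(
                    f"{self.path.name} line {lineno}: {exc}"
                ) from exc
            if record.mapq < self.min_mapq or record.read_length < self.min_read_length:
                self.skipped_filtered += 1
                continue
            yield record


def parse_gaf(
    path: str | Path, min_mapq: int = 0, min_read_length: int = 0
) -> GafReader:
    """Open a GAF file for streaming; see :class:`GafReader`."""
    return GafReader(path, min_mapq=min_mapq, min_read_length=min_read_length)


def write_sv_table(calls: Sequence, path: str | Path) -> None:
    """Write SV calls as a deterministic TSV.

    Rows are sorted by (step pair, called node string, SV type) so identical
    call lists always produce byte-identical files.
    """
    header = (
        "sv_type\tstep_from\tstep_to\tcalled_node\tmotif_nodes"
        "\tlfc_values\tevidence\n"
    )
    rows = []
    for call in calls:
        called = ";".join(call.called_nodes)
        motif_nodes = ",".join(call.motif_nodes)
        lfc = ",".join(f"{v:.6g}" for v in call.outlier_lfc)
        rows.append(
            (
                call.step_pair,
                called,
                call.sv_type,
                f"{call.sv_type}\t{call.step_pair - 1}\t{call.step_pair}"
                f"\t{called}\t{motif_nodes}\t{lfc}\t{call.motif}\n",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as out:
        out.write(header)
        for _, _, _, line in rows:
            out.write(line)


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _blend(a: str, b: str, frac: float) -> str:
    ra, ga, ba = _hex_to_rgb(a)
    rb, gb, bb = _hex_to_rgb(b)
    mix = (round(ra + (rb - ra) * frac), round(ga + (gb - ga) * frac), round(ba + (bb - ba) * frac))
    return "#{:02X}{:02X}{:02X}".format(*mix)


def lfc_to_colour(value: float, scale_max: float) -> str:
    """Map a log fold change onto the diverging ramp.

    0 maps to the midpoint colour; ``+scale_max``/``-scale_max`` map to the
    ramp ends.  ``scale_max`` <= 0 means every node is at the midpoint.
    """
    if scale_max <= 0 or value == 0:
        return BANDAGE_MID
    frac = min(abs(value) / scale_max, 1.0)
    return _blend(BANDAGE_MID, BANDAGE_HIGH if value > 0 else BANDAGE_LOW, frac)


def write_bandage_csv(graph, lfc, step_pair: int, path: str | Path) -> None:
    """Write a Bandage ``Name,Colour`` overlay for one step pair.

    Node colours come from the diverging ramp on that step pair's node log
    fold change, symmetric about zero and scaled by the largest magnitude in
    the step (all-zero steps render uniformly at the midpoint colour).
    """
    row = lfc.node_lfc.loc[step_pair]
    scale_max = float(abs(row).max()) if len(row) else 0.0
    with open(path, "w") as out:
        out.write("Name,Colour\n")
        for node in sorted(graph.nodes()):
            out.write(f"{node},{lfc_to_colour(float(row[node]), scale_max)}\n")
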