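"""Desk-scale synthetic fixtures: graphs, alignments, and truth tables.

The generator emulates what a long-read metagenome coassembly leaves behind
at graph level: backbone chains of segments (shared genome sequence), with
SV motifs implanted on top —

* insertion/deletion: a bubble (variant node between two flanks that also
  share a direct edge, i.e. a triangle) whose variant-node depth shifts by a
  configured fold between two consecutive samples while the flanks follow
  the genome's abundance;
* complex indel: a square (two parallel one-node paths between flanks, no
  direct flank edge) whose two interior nodes move in opposite directions;
* tandem duplication: a self-loop (or a weight-2 parallel edge) whose
  traversal count jumps by the configured fold.

Per-sample GAF alignments realise the requested depths: reads tile each
node (mean depth within half a read of target), and junction reads walk
loops/parallel edges to realise traversal counts exactly.  Everything is
driven by one seed; identical configs give byte-identical files.

Fixtures are graph-level by design: no base-calling error model and no
assembler in the loop, because the caller consumes only GFA + GAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .caller import SVCall, SV_TYPES
from .errors import GraphSVError
from .graphio import AssemblyGraph, LinkRecord, SegmentRecord, write_gfa

Mixture = Literal["variant_only", "mixed"]


@dataclass(frozen=True)
class SVEvent:
    """One implanted SV.

    ``step`` is the step pair n at which the change happens (t_{n-1} to
    t_n); the change persists for the rest of the series.  ``fold`` is the
    depth (or traversal-count) ratio across the step; explicit per-sample
    ``depth_a``/``depth_b``/``loop_counts`` profiles override the
    fold-derived defaults (``depth_b`` is the declining node of a complex
    indel; ``loop_counts`` the duplication junction traversals).
    """

    sv_type: str
    step: int
    backbone: int = 0
    fold: float = 4.0
    motif: str | None = None
    depth_a: tuple[float, ...] | None = None
    depth_b: tuple[float, ...] | None = None
    loop_counts: tuple[int, ...] | None = None

    def resolved_motif(self) -> str:
        if self.motif is not None:
            return self.motif
        if self.sv_type in ("insertion", "deletion"):
            return "triangle"
        if self.sv_type == "complex_indel":
            return "square"
        return "self_loop"


@dataclass
class FixtureConfig:
    """Study-condition knobs for one synthetic series.

    ``backbone_nodes`` is per backbone; each event occupies one two-flank
    slot, so a backbone supports floor((backbone_nodes - 1) / 2) events.
    ``depth_base`` is mean read depth at relative abundance 1;
    ``backbone_abundance`` (per backbone, per sample) scales it.
    ``noise_sd`` is the sd of a lognormal multiplicative depth noise applied
    per node per sample (0 = noiseless).
    """

    seed: int = 0
    n_samples: int = 2
    n_backbones: int = 1
    backbone_nodes: int = 21
    backbone_length_range: tuple[int, int] = (1000, 5000)
    event_length_range: tuple[int, int] = (500, 2000)
    events: tuple[SVEvent, ...] = ()
    depth_base: float = 10.0
    read_length: int = 1000
    noise_sd: float = 0.0
    loop_base: int = 2
    backbone_abundance: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        if self.n_samples < 2:
            raise GraphSVError("fixture needs >= 2 samples")
        for ev in self.events:
            if ev.sv_type not in SV_TYPES:
                raise GraphSVError(f"unknown sv_type {ev.sv_type!r}")
            if not (1 <= ev.step <= self.n_samples - 1):
                raise GraphSVError(f"event step {ev.step} outside series")
            if not (0 <= ev.backbone < self.n_backbones):
                raise GraphSVError(f"event backbone {ev.backbone} out of range")
            if ev.fold <= 1:
                raise GraphSVError("implanted fold change must be > 1")
        if self.backbone_abundance is not None:
            if len(self.backbone_abundance) != self.n_backbones:
                raise GraphSVError("backbone_abundance needs one row per backbone")
            for row in self.backbone_abundance:
                if len(row) != self.n_samples:
                    raise GraphSVError("backbone_abundance rows need one entry per sample")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"t{i}" for i in range(self.n_samples))


@dataclass
class Fixture:
    """Built fixture: file paths, truth table, and requested depths."""

    gfa_path: Path
    gaf_paths: list[Path]
    truth: pd.DataFrame
    depth: pd.DataFrame  # requested mean depth [sample x node], noiseless part
    config: FixtureConfig


def _step_profile(pre: float, post: float, step: int, n: int) -> np.ndarray:
    prof = np.full(n, float(pre))
    prof[step:] = float(post)
    return prof


def build_fixture(config: FixtureConfig, outdir: str | Path) -> Fixture:
    """Generate GFA, per-sample GAF files and the truth table under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    abundance = config.backbone_abundance or tuple(
        tuple(1.0 for _ in range(n)) for _ in range(config.n_backbones)
    )

    asm = AssemblyGraph()
    # node -> noiseless per-sample target depth from read tiling
    base_depth: dict[str, np.ndarray] = {}
    # (path nodes, per-sample counts): junction reads realising traversals
    junction_reads: list[tuple[tuple[str, str], np.ndarray]] = []
    truth_rows: list[dict] = []

    def add_segment(name: str, length: int) -> None:
        asm.segments[name] = SegmentRecord(name=name, length=int(length))

    def add_link(a: str, b: str, oa: str = "+", ob: str = "+") -> None:
        asm.links.append(LinkRecord(a, oa, b, ob))

    lo, hi = config.backbone_length_range
    backbone_names: list[list[str]] = []
    for b in range(config.n_backbones):
        names = [f"g{b}n{i:03d}" for i in range(config.backbone_nodes)]
        lengths = rng.integers(lo, hi + 1, size=config.backbone_nodes)
        for name, length in zip(names, lengths):
            add_segment(name, length)
            base_depth[name] = config.depth_base * np.asarray(abundance[b], dtype=float)
        backbone_names.append(names)

    # assign each event a two-flank slot on its backbone, in config order
    slot_counter = [0] * config.n_backbones
    complex_slots: set[tuple[int, int]] = set()
    elo, ehi = config.event_length_range
    for idx, ev in enumerate(config.events):
        b = ev.backbone
        j = slot_counter[b]
        slot_counter[b] += 1
        if 2 * j + 1 >= config.backbone_nodes:
            raise GraphSVError(
                f"backbone {b}: {slot_counter[b]} events exceed capacity "
                f"({config.backbone_nodes} nodes)"
            )
        f1, f2 = backbone_names[b][2 * j], backbone_names[b][2 * j + 1]
        S = config.depth_base * np.asarray(abundance[b], dtype=float)
        motif = ev.resolved_motif()
        prefix = f"g{b}s{j}"
        if ev.sv_type in ("insertion", "deletion"):
            v = f"{prefix}v"
            add_segment(v, rng.integers(elo, ehi + 1))
            add_link(f1, v)
            add_link(v, f2)
            if ev.depth_a is not None:
                base_depth[v] = np.asarray(ev.depth_a, dtype=float)
            elif ev.sv_type == "insertion":
                base_depth[v] = S * _step_profile(1.0, ev.fold, ev.step, n)
            else:
                base_depth[v] = S * _step_profile(1.0, 1.0 / ev.fold, ev.step, n)
            truth_rows.append(
                dict(sv_type=ev.sv_type, step_pair=ev.step, nodes=v, motif=motif)
            )
        elif ev.sv_type == "complex_indel":
            a, c = f"{prefix}a", f"{prefix}b"
            add_segment(a, rng.integers(elo, ehi + 1))
            add_segment(c, rng.integers(elo, ehi + 1))
            add_link(f1, a)
            add_link(a, f2)
            add_link(f1, c)
            add_link(c, f2)
            complex_slots.add((b, j))
            base_depth[a] = (
                np.asarray(ev.depth_a, dtype=float)
                if ev.depth_a is not None
                else S * _step_profile(1.0, ev.fold, ev.step, n)
            )
            base_depth[c] = (
                np.asarray(ev.depth_b, dtype=float)
                if ev.depth_b is not None
                else S * _step_profile(1.0, 1.0 / ev.fold, ev.step, n)
            )
            truth_rows.append(
                dict(
                    sv_type=ev.sv_type,
                    step_pair=ev.step,
                    nodes=f"{a};{c}",
                    motif=motif,
                )
            )
        elif ev.sv_type == "tandem_duplication":
            counts = (
                np.asarray(ev.loop_counts, dtype=int)
                if ev.loop_counts is not None
                else np.rint(
                    config.loop_base * _step_profile(1.0, ev.fold, ev.step, n)
                ).astype(int)
            )
            d = f"{prefix}d"
            add_segment(d, rng.integers(elo, ehi + 1))
            add_link(f1, d)
            if motif == "self_loop":
                add_link(d, d)
                base_depth[d] = (
                    np.asarray(ev.depth_a, dtype=float) if ev.depth_a is not None else S.copy()
                )
                junction_reads.append(((d, d), counts))
                called = d
            elif motif == "parallel_edge":
                e = f"{prefix}e"
                add_segment(e, rng.integers(elo, ehi + 1))
                add_link(d, e, "+", "+")
                add_link(d, e, "+", "-")
                base_depth[d] = S.copy()
                base_depth[e] = (
                    np.asarray(ev.depth_a, dtype=float)
                    if ev.depth_a is not None
                    else S * _step_profile(1.0, ev.fold, ev.step, n)
                )
                junction_reads.append(((d, e), counts))
                called = e
            else:
                raise GraphSVError(f"unknown duplication motif {motif!r}")
            truth_rows.append(
                dict(sv_type=ev.sv_type, step_pair=ev.step, nodes=called, motif=motif)
            )
        else:  # pragma: no cover - guarded in __post_init__
            raise GraphSVError(ev.sv_type)

    # backbone chain edges, skipping flank pairs replaced by a square
    for b, names in enumerate(backbone_names):
        for i in range(len(names) - 1):
            if i % 2 == 0 and (b, i // 2) in complex_slots:
                continue
            add_link(names[i], names[i + 1])

    # requested depth = tiled base depth + junction-read contributions
    node_order = sorted(asm.segments)
    requested = pd.DataFrame(
        {node: base_depth[node] for node in node_order},
        index=list(config.sample_ids),
    )
    for path_nodes, counts in junction_reads:
        for node in path_nodes:
            requested[node] = requested[node] + counts

    gfa_path = outdir / "graph.gfa"
    write_gfa(asm, gfa_path)

    noise = {}
    if config.noise_sd > 0:
        for node in node_order:
            noise[node] = np.exp(rng.normal(0.0, config.noise_sd, size=n))

    gaf_paths = []
    for t, sample in enumerate(config.sample_ids):
        gaf_path = outdir / f"{sample}.gaf"
        with open(gaf_path, "w") as out:
            for node in node_order:
                depth = base_depth[node][t]
                if node in noise:
                    depth *= noise[node][t]
                _write_tiled_reads(out, sample, node, asm.segments[node].length, depth, config.read_length)
            for k, (path_nodes, counts) in enumerate(junction_reads):
                total = sum(asm.segments[p].length for p in path_nodes)
                path_str = "".join(f">{p}" for p in path_nodes)
                for i in range(int(counts[t])):
                    _write_gaf_line(out, f"{sample}_j{k}_{i}", total, path_str, total, 0, total)
        gaf_paths.append(gaf_path)

    truth = pd.DataFrame(
        truth_rows, columns=["sv_type", "step_pair", "nodes", "motif"]
    )
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return Fixture(
        gfa_path=gfa_path,
        gaf_paths=gaf_paths,
        truth=truth,
        depth=requested,
        config=config,
    )


def _write_gaf_line(out, read_id: str, read_len: int, path_str: str, plen: int, pstart: int, pend: int) -> None:
    out.write(
        f"{read_id}\t{read_len}\t0\t{read_len}\t+\t{path_str}"
        f"\t{plen}\t{pstart}\t{pend}\t{read_len}\t{read_len}\t60\n"
    )


def _write_tiled_reads(out, sample: str, node: str, length: int, depth: float, read_length: int) -> None:
    """Tile single-segment reads so mean node depth approximates ``depth``."""
    rl = min(read_length, length)
    n_reads = int(round(depth * length / rl))
    if n_reads <= 0:
        return
    span = length - rl
    for i in range(n_reads):
        start = 0 if n_reads == 1 else int(round(i * span / (n_reads - 1)))
        _write_gaf_line(out, f"{sample}_{node}_{i}", rl, f">{node}", length, start, start + rl)


def evaluate_calls(
    calls: Sequence[SVCall], truth: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Per-type recall/precision of calls against a fixture truth table.

    A truth row counts as detected when some call of the same type and step
    pair shares at least one node with it; a call is a true positive when it
    matches at least one truth row.  The ``overall`` entry pools all types.
    """
    truth_sets = [
        (row.sv_type, int(row.step_pair), set(row.nodes.split(";")))
        for row in truth.itertuples()
    ]
    call_sets = [
        (c.sv_type, c.step_pair, set(c.called_nodes)) for c in calls
    ]

    def _matches(a, b) -> bool:
        return a[0] == b[0] and a[1] == b[1] and bool(a[2] & b[2])

    result: dict[str, dict[str, float]] = {}
    for sv_type in SV_TYPES + ("overall",):
        t_rows = [t for t in truth_sets if sv_type == "overall" or t[0] == sv_type]
        c_rows = [c for c in call_sets if sv_type == "overall" or c[0] == sv_type]
        detected = sum(any(_matches(t, c) for c in c_rows) for t in t_rows)
        tp_calls = sum(any(_matches(t, c) for t in t_rows) for c in c_rows)
        result[sv_type] = {
            "recall": detected / len(t_rows) if t_rows else float("nan"),
            "precision": tp_calls / len(c_rows) if c_rows else float("nan"),
            "n_truth": len(t_rows),
            "n_calls": len(c_rows),
        }
    return result


def build_recovery_design(
    seed: int = 0,
    n_per_type: int = 5,
    n_samples: int = 3,
    noise_sd: float = 0.0,
) -> FixtureConfig:
    """Fixture with ``n_per_type`` events of every SV type over a short series.

    Events alternate between step pairs; duplications mix self-loop and
    parallel-edge motifs.  Used for parameter-recovery checks: on noiseless
    input the caller must recover every event exactly.
    """
    events = []
    for sv_type in SV_TYPES:
        for k in range(n_per_type):
            motif = None
            if sv_type == "tandem_duplication":
                motif = "parallel_edge" if k % 3 == 2 else "self_loop"
            events.append(
                SVEvent(
                    sv_type=sv_type,
                    step=1 + (k % (n_samples - 1)),
                    fold=4.0,
                    motif=motif,
                )
            )
    n_events = len(events)
    return FixtureConfig(
        seed=seed,
        n_samples=n_samples,
        n_backbones=1,
        backbone_nodes=2 * n_events + 1,
        events=tuple(events),
        noise_sd=noise_sd,
    )


N_HGT_DONORS = 10
N_HGT_RECIPIENTS = 10


def build_hgtsim_design(mutation_rate_label: str, seed: int = 0) -> FixtureConfig:
    """Graph-level analogue of the HGT simulation design.

    Ten donor genomes each contribute one gene, inserted into each of ten
    recipient genomes: 100 insertion events across one step pair.  All
    species share equal abundance before the transfer; post-transfer
    relative quantities are drawn uniformly from {1..5} per species.  The
    mutation-rate label (``m0``/``m30``) changes inserted-sequence identity
    only, not the event set, so both labels map to the same graph design.
    """
    if mutation_rate_label not in ("m0", "m30"):
        raise GraphSVError(f"unknown design label {mutation_rate_label!r}")
    rng = np.random.default_rng(seed)
    n_species = N_HGT_DONORS + N_HGT_RECIPIENTS
    quantity = rng.integers(1, 6, size=n_species)
    abundance = tuple((1.0, float(q)) for q in quantity)
    depth_base = 10.0
    events = []
    for r in range(N_HGT_DONORS, n_species):
        q = float(quantity[r])
        for _ in range(N_HGT_DONORS):
            events.append(
                SVEvent(
                    sv_type="insertion",
                    step=1,
                    backbone=r,
                    fold=2.0,
                    depth_a=(0.0, depth_base * q),
                )
            )
    return FixtureConfig(
        seed=seed,
        n_samples=2,
        n_backbones=n_species,
        backbone_nodes=2 * N_HGT_DONORS + 1,
        events=tuple(events),
        depth_base=depth_base,
        backbone_abundance=abundance,
    )


N_ZYMO_GENOMES = 10
ZYMO_INDELS_PER_GENOME = 20
ZYMO_DUPS_PER_GENOME = 10
ZYMO_COMPLEX_PER_GENOME = 10


def build_zymo_design(seed: int = 0) -> FixtureConfig:
    """Graph-level analogue of the mock-community SV simulation.

    Ten genome backbones each receive 20 indels (random insertion/deletion
    split), 10 tandem duplications and 10 complex indels, 400 events total,
    variant segment lengths 500–2000 bp.  At the post-transfer sample half
    the genomes carry only their variant strain and half an equal mix of
    variant and original, which halves every variant depth shift.
    """
    rng = np.random.default_rng(seed)
    depth_base = 10.0
    events = []
    for g in range(N_ZYMO_GENOMES):
        mixture: Mixture = "variant_only" if g < N_ZYMO_GENOMES // 2 else "mixed"
        frac = 1.0 if mixture == "variant_only" else 0.5
        S = depth_base
        for _ in range(ZYMO_INDELS_PER_GENOME):
            if rng.integers(0, 2) == 0:
                events.append(
                    SVEvent(
                        sv_type="insertion",
                        step=1,
                        backbone=g,
                        fold=2.0,
                        depth_a=(0.0, S * frac),
                    )
                )
            else:
                events.append(
                    SVEvent(
                        sv_type="deletion",
                        step=1,
                        backbone=g,
                        fold=2.0,
                        depth_a=(S, S * (1.0 - frac)),
                    )
                )
        for _ in range(ZYMO_DUPS_PER_GENOME):
            events.append(
                SVEvent(
                    sv_type="tandem_duplication",
                    step=1,
                    backbone=g,
                    fold=2.0,
                    loop_counts=(0, int(8 * frac)),
                )
            )
        for _ in range(ZYMO_COMPLEX_PER_GENOME):
            events.append(
                SVEvent(
                    sv_type="complex_indel",
                    step=1,
                    backbone=g,
                    fold=2.0,
                    depth_a=(0.0, S * frac),
                    depth_b=(S, S * (1.0 - frac)),
                )
            )
    per_genome = ZYMO_INDELS_PER_GENOME + ZYMO_DUPS_PER_GENOME + ZYMO_COMPLEX_PER_GENOME
    return FixtureConfig(
        seed=seed,
        n_samples=2,
        n_backbones=N_ZYMO_GENOMES,
        backbone_nodes=2 * per_genome + 1,
        events=tuple(events),
        depth_base=depth_base,
    )
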