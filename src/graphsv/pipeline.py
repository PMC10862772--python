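"""End-to-end orchestration: inputs -> coverage -> fold change -> SV calls.

The internal path consumes a precomputed coassembly graph (GFA) plus one GAF
per sample.  The external path pools raw reads from all samples into one
assembler invocation (haplotype-keeping flag on, so strain variants survive
as bubbles) and aligns each sample back separately; it requires the
``flye`` and ``minigraph`` binaries on PATH and is never reimplemented here.

Every run serialises a manifest (inputs, options, versions, seed) alongside
its outputs so it can be reproduced bit for bit given the same binaries.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .caller import CallResult, call_all
from .coverage import SeriesConfig, compute_coverage
from .errors import GraphSVError
from .foldchange import compute_lfc
from .graph import collapse
from .graphio import parse_gaf, parse_gfa, write_bandage_csv, write_sv_table

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run.

    Exactly one of (``graph_path`` + ``alignment_paths``) or ``read_paths``
    must be supplied; series order of the per-sample lists is the series
    order of the analysis.
    """

    out_dir: str
    graph_path: str | None = None
    alignment_paths: tuple[str, ...] = ()
    read_paths: tuple[str, ...] = ()
    read_type: str = "nano-raw"
    sample_ids: tuple[str, ...] = ()
    log_base: float = 2.0
    floor_value: float = 1.0
    normalization_mode: str = "median_ratio"
    sd_mode: str = "population"
    min_mapq: int = 0
    min_read_length: int = 0
    seed: int = 0
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alignment_paths = tuple(str(p) for p in self.alignment_paths)
        self.read_paths = tuple(str(p) for p in self.read_paths)
        has_graph = self.graph_path is not None and self.alignment_paths
        if bool(has_graph) == bool(self.read_paths):
            raise GraphSVError(
                "supply either --graph with one alignment per sample, or raw reads"
            )
        n = len(self.alignment_paths) or len(self.read_paths)
        if n < 2:
            raise GraphSVError("a series needs at least 2 samples (no step pairs)")
        if not self.sample_ids:
            self.sample_ids = tuple(
                Path(p).stem for p in (self.alignment_paths or self.read_paths)
            )
        if self.sd_mode not in ("population", "sample"):
            raise GraphSVError(f"unknown sd mode {self.sd_mode!r}")
        self.versions.setdefault("graphsv", __version__)
        self.versions.setdefault("python", sys.version.split()[0])


@dataclass
class RunResult:
    manifest: RunManifest
    calls: CallResult
    outputs: dict[str, str]


def _require_binary(name: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise GraphSVError(
            f"external binary {name!r} not found on PATH; install it or supply "
            "a precomputed graph (--graph) and per-sample alignments (--aln)"
        )
    return path


def _binary_version(name: str) -> str:
    try:
        proc = subprocess.run(
            [name, "--version"], capture_output=True, text=True, timeout=60
        )
        return (proc.stdout or proc.stderr).strip().splitlines()[0]
    except Exception:  # pragma: no cover - defensive
        return "unknown"


def _assemble_and_align(manifest: RunManifest, workdir: Path) -> tuple[Path, list[Path]]:
    """External path: pooled assembly, then per-sample alignment.

    All samples' reads feed one assembly so shared sequence collapses into a
    single coassembly graph; ``--keep-haplotypes`` preserves strain bubbles.
    """
    flye = _require_binary("flye")
    minigraph = _require_binary("minigraph")
    manifest.versions["flye"] = _binary_version("flye")
    manifest.versions["minigraph"] = _binary_version("minigraph")
    asm_dir = workdir / "assembly"
    cmd = [
        flye,
        f"--{manifest.read_type}",
        *manifest.read_paths,
        "--keep-haplotypes",
        "--meta",
        "--out-dir",
        str(asm_dir),
    ]
    logger.info("assembly: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    graph = asm_dir / "assembly_graph.gfa"
    gafs = []
    for sample, reads in zip(manifest.sample_ids, manifest.read_paths):
        gaf = workdir / f"{sample}.gaf"
        cmd = [minigraph, "-cx", "lr", str(graph), str(reads)]
        logger.info("alignment: %s > %s", " ".join(cmd), gaf)
        with open(gaf, "w") as out:
            subprocess.run(cmd, check=True, stdout=out)
        gafs.append(gaf)
    return graph, gafs


def run_call(manifest: RunManifest) -> RunResult:
    """Execute the full pipeline described by ``manifest``."""
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if manifest.read_paths:
        graph_path, gaf_paths = _assemble_and_align(manifest, out_dir)
    else:
        graph_path = Path(manifest.graph_path)  # type: ignore[arg-type]
        gaf_paths = [Path(p) for p in manifest.alignment_paths]

    graph = collapse(parse_gfa(graph_path))
    config = SeriesConfig(
        sample_ids=manifest.sample_ids,
        log_base=manifest.log_base,
        floor_value=manifest.floor_value,
        normalization_mode=manifest.normalization_mode,  # type: ignore[arg-type]
    )
    streams = [
        parse_gaf(p, min_mapq=manifest.min_mapq, min_read_length=manifest.min_read_length)
        for p in gaf_paths
    ]
    cov, config = compute_coverage(graph, streams, config)
    lfc = compute_lfc(cov, config)
    ddof = 0 if manifest.sd_mode == "population" else 1
    result = call_all(graph, lfc, ddof=ddof)

    outputs: dict[str, str] = {}

    sv_path = out_dir / "sv_calls.tsv"
    write_sv_table(result.calls, sv_path)
    outputs["sv_calls"] = str(sv_path)

    for name, frame in (
        ("node_coverage", cov.node_cov),
        ("edge_coverage", cov.edge_cov),
        ("node_lfc", lfc.node_lfc),
        ("edge_lfc", lfc.edge_lfc),
    ):
        path = out_dir / f"{name}.tsv"
        frame.T.to_csv(path, sep="\t")
        outputs[name] = str(path)

    for step in lfc.node_lfc.index:
        path = out_dir / f"bandage_step_{int(step)}.csv"
        write_bandage_csv(graph, lfc, int(step), path)
        outputs[f"bandage_step_{int(step)}"] = str(path)

    summary = {
        "n_samples": len(manifest.sample_ids),
        "n_nodes": len(graph.nodes()),
        "n_edges": len(graph.edges()),
        "bp_totals": list(config.bp_totals or ()),
        "off_graph_adjacencies": cov.off_graph,
        "calls_per_step": result.summary(),
        "motif_instances_per_step": result.motif_counts,
        "n_calls": len(result.calls),
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    outputs["summary"] = str(summary_path)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = str(manifest_path)

    logger.info(
        "called %d SVs across %d step pair(s)", len(result.calls), config.n_steps
    )
    return RunResult(manifest=manifest, calls=result, outputs=outputs)
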